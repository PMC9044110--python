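"""Graded response model: curves, likelihood, calibration, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from adosdif.grm import (
    EMSettings,
    GRMItemParams,
    QuadratureGrid,
    category_probabilities,
    cumulative_probability,
    eap_scores,
    expected_item_score,
    expected_test_score,
    fit_grm,
    fit_multigroup_grm,
    marginal_log_likelihood,
    tabulate_icc,
)
from adosdif.synthetic import PlantedDIF, make_clinic_design, simulate_dataset
from conftest import fixed_param_design

params_strategy = st.builds(
    lambda a, b1, gap: GRMItemParams(a=a, b=(b1, b1 + gap)),
    a=st.floats(0.2, 4.0),
    b1=st.floats(-3.0, 2.0),
    gap=st.floats(0.1, 3.0),
)


class TestCurves:
    def test_reference_values(self):
        p = GRMItemParams(a=2.0, b=(-1.0, 1.0))
        assert cumulative_probability(p, 1, 0.0) == pytest.approx(0.8808, abs=1e-4)
        assert cumulative_probability(p, 2, 0.0) == pytest.approx(0.1192, abs=1e-4)
        assert np.allclose(
            category_probabilities(p, 0.0), [0.1192, 0.7616, 0.1192], atol=1e-4
        )
        assert expected_item_score(p, 0.0) == pytest.approx(1.0)

    def test_threshold_located_at_half_probability(self):
        # a dichotomous item with b1=0 crosses 0.5 exactly at theta=0
        p = GRMItemParams(a=3.53, b=(0.0, 1.34))
        assert cumulative_probability(p, 1, 0.0) == pytest.approx(0.5)

    def test_low_discrimination_expected_score(self):
        # closed form: E[X|theta] = sum_k logistic(a (theta - b_k))
        p = GRMItemParams(a=0.54, b=(0.69, 1.86))
        theta = 0.69
        expected = 0.5 + expit(0.54 * (0.69 - 1.86))
        assert expected_item_score(p, theta) == pytest.approx(expected, abs=1e-12)

    def test_limits(self):
        p = GRMItemParams(a=2.0, b=(-1.0, 1.0))
        assert cumulative_probability(p, 1, 50.0) == pytest.approx(1.0)
        assert expected_item_score(p, -50.0) == pytest.approx(0.0, abs=1e-12)

    def test_category_index_out_of_range(self):
        p = GRMItemParams(a=1.0, b=(0.0,))
        with pytest.raises(ValueError, match="out of range"):
            cumulative_probability(p, 2, 0.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=params_strategy, theta=st.floats(-6.0, 6.0))
    def test_normalization_and_bounds(self, p, theta):
        probs = category_probabilities(p, theta)
        assert probs.shape == (3,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=params_strategy)
    def test_expected_score_monotone_in_theta(self, p):
        grid = np.linspace(-6, 6, 61)
        e = expected_item_score(p, grid)
        assert np.all(np.diff(e) >= 0)

    def test_symmetric_item_symmetric_extremes(self):
        p = GRMItemParams(a=1.7, b=(-0.8, 0.8))
        probs = category_probabilities(p, 0.0)
        assert probs[0] == pytest.approx(probs[2])

    def test_dichotomous_vector_length(self):
        p = GRMItemParams(a=1.0, b=(0.3,))
        assert category_probabilities(p, 0.0).shape == (2,)


class TestExpectedTestScore:
    def test_additivity_and_identity(self):
        p = GRMItemParams(a=2.0, b=(-1.0, 1.0))
        assert expected_test_score([p] * 14, 0.0) == pytest.approx(14.0)
        assert expected_test_score([p], 0.7) == pytest.approx(
            expected_item_score(p, 0.7)
        )

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(12)
        items = [
            GRMItemParams(a=rng.uniform(0.5, 3), b=(b1, b1 + rng.uniform(0.2, 2)))
            for b1 in rng.uniform(-2, 1, size=10)
        ]
        thetas = rng.normal(size=100)
        total = expected_test_score(items, thetas)
        brute = np.zeros(100)
        for p in items:
            for i, th in enumerate(thetas):
                brute[i] += expected_item_score(p, th)
        assert np.allclose(total, brute, atol=1e-12)

    def test_maximum_equals_sum_of_top_categories(self):
        items = [GRMItemParams(a=2.0, b=(-1.0, 1.0))] * 13 + [
            GRMItemParams(a=2.0, b=(0.0,))
        ]
        assert expected_test_score(items, 60.0) == pytest.approx(27.0, abs=1e-6)


class TestMarginalLogLikelihood:
    def test_single_dichotomous_symmetric(self, grid):
        ll = marginal_log_likelihood(
            np.array([[1]]), [GRMItemParams(1.0, (0.0,))], grid
        )
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_duplicating_persons_doubles_ll(self, grid):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, size=(20, 3))
        params = [GRMItemParams(1.5, (-0.5, 0.5))] * 3
        ll1 = marginal_log_likelihood(x, params, grid)
        ll2 = marginal_log_likelihood(np.vstack([x, x]), params, grid)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-9)

    def test_matches_naive_triple_loop(self, grid):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, size=(5, 3))
        params = [
            GRMItemParams(1.2, (-0.5, 0.7)),
            GRMItemParams(0.8, (0.0, 1.0)),
            GRMItemParams(2.0, (-1.0, 0.2)),
        ]
        ll = marginal_log_likelihood(x, params, grid)
        brute = 0.0
        for i in range(5):
            acc = 0.0
            for q in range(len(grid.nodes)):
                prod = grid.weights[q]
                for j in range(3):
                    prod *= category_probabilities(params[j], grid.nodes[q])[x[i, j]]
                acc += prod
            brute += np.log(acc)
        assert ll == pytest.approx(brute, abs=1e-10)

    def test_grid_refinement_agreement(self, small_dataset, small_design):
        ds, _, _ = small_dataset
        x = ds.responses[:50]
        plist = [small_design.ref_params[i] for i in small_design.spec.item_names]
        coarse = marginal_log_likelihood(x, plist, QuadratureGrid.normal(49))
        fine = marginal_log_likelihood(x, plist, QuadratureGrid.normal(199))
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_zero_probability_pattern_fatal(self, grid):
        # a response above an item's top category has probability zero
        with pytest.raises(ValueError, match="top category"):
            marginal_log_likelihood(
                np.array([[2]]), [GRMItemParams(1.0, (0.0,))], grid
            )


class TestFitGRM:
    @pytest.fixture(scope="class")
    def recovery_fit(self, grid):
        design = fixed_param_design(a=1.5, b=(-1.0, 0.5),
                                    n_reference=2500, n_focal=2500, seed=7)
        ds, thetas, _ = simulate_dataset(design)
        fit = fit_grm(ds, grid, EMSettings(compute_se=True))
        return design, ds, thetas, fit

    def test_parameter_recovery(self, recovery_fit):
        design, _, _, fit = recovery_fit
        for item in design.spec.item_names:
            p = fit.params[item]
            assert p.a == pytest.approx(1.5, abs=0.15)
            assert p.b[0] == pytest.approx(-1.0, abs=0.10)
            assert p.b[1] == pytest.approx(0.5, abs=0.10)

    def test_ll_trace_nondecreasing(self, recovery_fit):
        *_, fit = recovery_fit
        assert np.all(np.diff(fit.ll_trace) >= -1e-8)

    def test_fit_dominates_truth(self, recovery_fit, grid):
        design, ds, _, fit = recovery_fit
        truth = [design.ref_params[i] for i in design.spec.item_names]
        ll_truth = marginal_log_likelihood(ds, truth, grid)
        assert fit.log_likelihood >= ll_truth

    def test_standard_errors_shrink_with_n(self, recovery_fit, grid):
        design, ds, _, fit = recovery_fit
        small = fit_grm(ds.responses[:400], grid, EMSettings(compute_se=True))
        item_small = "item_1"
        item_big = design.spec.item_names[0]
        assert fit.standard_errors[item_big]["a"] < small.standard_errors[item_small]["a"]

    def test_degenerate_item_excluded_with_warning(self, grid):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=(200, 3))
        x[:, 1] = 1  # constant item
        with pytest.warns(UserWarning, match="<2 observed categories"):
            fit = fit_grm(x, grid)
        assert "item_2" in fit.excluded_items
        assert len(fit.params) == 2


class TestEAP:
    def test_extreme_patterns_ordered(self, grid):
        params = {f"item_{j+1}": GRMItemParams(1.5, (-0.5, 0.5)) for j in range(5)}
        x = np.vstack([np.zeros(5, int), np.full(5, 2)])
        est = eap_scores(x, params, grid)
        assert est.eap[0] < 0 < est.eap[1]
        assert np.all(est.eap >= grid.nodes.min())
        assert np.all(est.eap <= grid.nodes.max())

    def test_uninformative_items_return_prior_mean(self, grid):
        params = {f"item_{j+1}": GRMItemParams(1e-3, (-0.5, 0.5)) for j in range(5)}
        x = np.vstack([np.zeros(5, int), np.full(5, 2)])
        est = eap_scores(x, params, grid)
        assert np.allclose(est.eap, 0.0, atol=0.01)
        assert np.allclose(est.psd, 1.0, atol=0.02)

    def test_recovery_correlation(self, grid):
        design = make_clinic_design("race", "3", seed=21,
                                    n_reference=1500, n_focal=1500,
                                    a_range=(1.0, 2.5))
        ds, thetas, _ = simulate_dataset(design)
        fit = fit_grm(ds, grid, EMSettings(compute_se=False))
        est = eap_scores(ds, fit, grid)
        assert np.corrcoef(est.eap, thetas)[0, 1] >= 0.85


class TestMultigroup:
    def test_null_dif_recovery(self, grid):
        design = make_clinic_design("race", "3", seed=31,
                                    n_reference=2000, n_focal=2000,
                                    a_range=(1.0, 2.5))
        ds, _, group = simulate_dataset(design)
        items = list(design.spec.item_names)
        free = ["sensory_interest"]
        anchors = [i for i in items if i not in free]
        fit = fit_multigroup_grm(ds, group, anchors, free, grid,
                                 EMSettings(compute_se=False))
        assert abs(fit.focal_mean) <= 0.08
        ref_p = fit.group_params["reference"]["sensory_interest"]
        foc_p = fit.group_params["focal"]["sensory_interest"]
        assert ref_p.a == pytest.approx(foc_p.a, abs=0.2)
        for br, bf in zip(ref_p.b, foc_p.b):
            assert br == pytest.approx(bf, abs=0.2)

    def test_anchor_params_shared_exactly(self, grid, small_dataset):
        ds, _, group = small_dataset
        items = list(ds.spec.item_names)
        fit = fit_multigroup_grm(ds, group, items[:-1], [items[-1]], grid,
                                 EMSettings(compute_se=False))
        for item in items[:-1]:
            assert fit.group_params["reference"][item] is fit.group_params["focal"][item]

    def test_planted_uniform_dif_direction(self, grid):
        hits = 0
        n_reps = 12
        ss = np.random.SeedSequence(77).generate_state(n_reps)
        for s in ss:
            seed = int(s % (2**31 - 1))
            design = make_clinic_design(
                "race", "3", seed=seed, n_reference=500, n_focal=500,
                a_range=(1.0, 2.5),
                planted_dif=[PlantedDIF("repetitive_interest", "uniform", 0.6)],
            )
            ds, _, group = simulate_dataset(design)
            items = list(design.spec.item_names)
            anchors = [i for i in items if i != "repetitive_interest"]
            fit = fit_multigroup_grm(ds, group, anchors, ["repetitive_interest"],
                                     grid, EMSettings(compute_se=False))
            ref_b = fit.group_params["reference"]["repetitive_interest"].b
            foc_b = fit.group_params["focal"]["repetitive_interest"].b
            if all(bf > br for br, bf in zip(ref_b, foc_b)):
                hits += 1
        assert hits >= int(0.9 * n_reps)

    def test_no_anchors_fatal(self, grid, small_dataset):
        ds, _, group = small_dataset
        with pytest.raises(ValueError, match="anchor"):
            fit_multigroup_grm(ds, group, [], list(ds.spec.item_names), grid)


class TestTabulateICC:
    def test_identical_params_identical_curves(self):
        params = {"gaze": GRMItemParams(2.0, (-0.5, 0.5))}
        table = tabulate_icc({"ref": params, "foc": dict(params)},
                             np.linspace(-3, 3, 13))
        ref = table[table.group == "ref"].drop(columns="group").reset_index(drop=True)
        foc = table[table.group == "foc"].drop(columns="group").reset_index(drop=True)
        assert ref.equals(foc)

    def test_probabilities_normalized_at_every_point(self):
        params = {"x": GRMItemParams(1.3, (-1.0, 0.4))}
        table = tabulate_icc({"g": params}, np.linspace(-4, 4, 9))
        sums = table.groupby("theta")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_uniform_dif_is_horizontal_shift_dichotomous(self):
        shift = 0.7
        ref = GRMItemParams(1.5, (0.0,))
        foc = GRMItemParams(1.5, (shift,))
        grid_theta = np.linspace(-3, 3, 25)
        p_ref = category_probabilities(ref, grid_theta + shift)[:, 1]
        p_foc = category_probabilities(foc, grid_theta + 0.0)[:, 1]
        # focal curve equals the reference curve translated by the shift
        assert np.allclose(category_probabilities(foc, grid_theta)[:, 1],
                           category_probabilities(ref, grid_theta - shift)[:, 1],
                           atol=1e-12)
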