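"""DIF detection battery: nested ordinal regressions, effect sizes, anchors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2, kstest

from adosdif.dif import (
    MagnitudeFlags,
    OLRModelTriple,
    classify_dif,
    delta_beta,
    dtf,
    essd,
    fit_olr_triple,
    irt_lr_dif,
    lr_tests,
    pseudo_r2_delta,
    purify_anchors,
)
from adosdif.grm import EMSettings, GRMItemParams, QuadratureGrid
from adosdif.synthetic import PlantedDIF, make_clinic_design, simulate_dataset


def _toy_ordinal(n=300, seed=0, beta_group=0.0):
    rng = np.random.default_rng(seed)
    theta = rng.normal(size=n)
    group = rng.integers(0, 2, size=n).astype(float)
    lin = 1.2 * theta + beta_group * group
    cuts = np.array([-0.7, 0.8])
    u = rng.random(n)
    p1 = expit(lin - cuts[0])
    p2 = expit(lin - cuts[1])
    y = (u < p2).astype(int) + (u < p1).astype(int)
    return y, theta, group


def _proportional_odds_nll(params, y, x, k):
    """Independent proportional-odds likelihood for the oracle refit."""
    n_beta = x.shape[1]
    beta = params[:n_beta]
    cuts = np.sort(params[n_beta:])
    lin = x @ beta
    cum = expit(lin[:, None] - cuts[None, :])  # P(Y > c)
    upper = np.column_stack([np.ones(len(y)), cum])
    lower = np.column_stack([cum, np.zeros(len(y))])
    p = np.clip(upper - lower, 1e-12, None)
    return -float(np.sum(np.log(p[np.arange(len(y)), y])))


class TestOLRTriple:
    def test_nesting_inequality(self):
        y, theta, group = _toy_ordinal(seed=3)
        t = fit_olr_triple(y, theta, group)
        assert t.ll_m1 <= t.ll_m2 + 1e-9
        assert t.ll_m2 <= t.ll_m3 + 1e-9

    def test_matches_generic_optimizer_oracle(self):
        y, theta, group = _toy_ordinal(n=80, seed=11, beta_group=0.6)
        t = fit_olr_triple(y, theta, group)
        for x_cols, ll in [
            (theta[:, None], t.ll_m1),
            (np.column_stack([theta, group]), t.ll_m2),
            (np.column_stack([theta, group, theta * group]), t.ll_m3),
        ]:
            k = 3
            best = np.inf
            for s in range(3):
                rng = np.random.default_rng(s)
                x0 = np.r_[rng.normal(0, 0.5, x_cols.shape[1]), -0.5, 0.5]
                res = minimize(_proportional_odds_nll, x0, args=(y, x_cols, k),
                               method="Nelder-Mead",
                               options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
                best = min(best, res.fun)
            assert ll == pytest.approx(-best, abs=1e-5)

    def test_permutation_null_p_values_uniform(self):
        """With the group label randomly permuted, no DIF is possible."""
        rng = np.random.default_rng(42)
        pvals = []
        y, theta, _ = _toy_ordinal(n=400, seed=5)
        for _ in range(60):
            group = rng.permutation(np.repeat([0.0, 1.0], 200))
            t = fit_olr_triple(y, theta, group)
            pvals.append(lr_tests(t)["p_total"])
        pvals = np.array(pvals)
        assert kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(pvals < 0.05) <= 0.15

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            fit_olr_triple(np.ones(50, int), np.zeros(50), np.repeat([0, 1], 25))
        with pytest.raises(ValueError, match="groups"):
            fit_olr_triple(np.tile([0, 1, 2], 10), np.zeros(30), np.zeros(30))


class TestLRTests:
    def _triple(self, ll1, ll2, ll3, ll_null=-100.0):
        return OLRModelTriple(ll_m1=ll1, ll_m2=ll2, ll_m3=ll3, ll_null=ll_null,
                              beta_theta_m1=1.0, beta_theta_m2=1.0,
                              beta_group_m2=0.0)

    def test_identical_lls_give_zero_chi2(self):
        out = lr_tests(self._triple(-50.0, -50.0, -50.0))
        assert out["chi2_total"] == 0.0
        assert out["p_total"] == 1.0

    def test_chi2_reference_quantile(self):
        out = lr_tests(self._triple(-50.0, -50.0 + 3.84 / 2, -50.0 + 3.84 / 2))
        assert out["p_uniform"] == pytest.approx(0.05, abs=0.001)

    def test_total_decomposes(self):
        out = lr_tests(self._triple(-60.0, -57.5, -55.2))
        assert out["chi2_total"] == pytest.approx(
            out["chi2_uniform"] + out["chi2_nonuniform"], abs=1e-8
        )

    def test_negative_statistic_fatal(self):
        bad = self._triple(-50.0, -50.0, -50.0)
        bad.ll_m2 = -51.0  # optimizer failure scenario
        with pytest.raises(RuntimeError, match="negative"):
            lr_tests(bad)


class TestPseudoR2AndDeltaBeta:
    def test_identity_cases(self):
        t = OLRModelTriple(-50.0, -50.0, -50.0, ll_null=-80.0,
                           beta_theta_m1=1.0, beta_theta_m2=1.0, beta_group_m2=0.0)
        r2 = pseudo_r2_delta(t)
        assert r2 == {"uniform": 0.0, "nonuniform": 0.0, "total": 0.0}
        assert delta_beta(t) == 0.0

    def test_telescoping(self):
        t = OLRModelTriple(-60.0, -58.0, -55.0, ll_null=-90.0,
                           beta_theta_m1=1.0, beta_theta_m2=1.1, beta_group_m2=0.2)
        r2 = pseudo_r2_delta(t)
        assert r2["total"] == pytest.approx(r2["uniform"] + r2["nonuniform"])

    def test_matches_independent_refit(self):
        y, theta, group = _toy_ordinal(n=200, seed=9, beta_group=0.8)
        t = fit_olr_triple(y, theta, group)
        counts = np.bincount(y)
        ll0 = float(np.sum(counts * np.log(counts / counts.sum())))
        assert t.ll_null == pytest.approx(ll0, abs=1e-10)
        r2 = pseudo_r2_delta(t)
        assert r2["uniform"] == pytest.approx(
            (1 - t.ll_m2 / ll0) - (1 - t.ll_m1 / ll0), abs=1e-12
        )

    def test_delta_beta_arithmetic(self):
        t = OLRModelTriple(-60.0, -58.0, -55.0, ll_null=-90.0,
                           beta_theta_m1=1.0, beta_theta_m2=0.88, beta_group_m2=0.3)
        db = delta_beta(t)
        assert db == pytest.approx(12.0)
        assert db > MagnitudeFlags().delta_beta_cutoff_pct

    def test_zero_theta_coefficient_flagged(self):
        t = OLRModelTriple(-60.0, -58.0, -55.0, ll_null=-90.0,
                           beta_theta_m1=0.0, beta_theta_m2=0.1, beta_group_m2=0.3)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(delta_beta(t))


class TestClassifyDIF:
    @pytest.mark.parametrize(
        "p_uniform,p_nonuniform,expected",
        [
            (0.30, 0.003, "nonuniform"),
            (0.01, 0.003, "nonuniform"),  # interaction takes precedence
            (0.01, 0.40, "uniform"),
            (0.40, 0.40, "none"),
        ],
    )
    def test_precedence_rules(self, p_uniform, p_nonuniform, expected):
        assert classify_dif(p_uniform, p_nonuniform, alpha=0.05) == expected


class TestESSD:
    def test_identical_parameters_give_zero(self):
        p = GRMItemParams(1.5, (-0.5, 0.5))
        thetas = np.linspace(-2, 2, 20)
        assert essd(p, p, thetas).essd == 0.0

    def test_hand_computed_dichotomous_case(self):
        # ref (a=1, b=0), focal (a=1, b=1), focal thetas {-1, 0, 1}
        out = essd(GRMItemParams(1.0, (0.0,)), GRMItemParams(1.0, (1.0,)), [-1, 0, 1])
        assert out.essd == pytest.approx(0.9604, abs=1e-4)

    def test_antisymmetric_under_group_swap(self):
        ref = GRMItemParams(1.2, (-0.3, 0.7))
        foc = GRMItemParams(1.2, (0.2, 1.2))
        thetas = np.linspace(-2, 2, 15)
        forward = essd(ref, foc, thetas).essd
        backward = essd(foc, ref, thetas).essd
        assert forward == pytest.approx(-backward)
        assert forward > 0  # higher focal difficulty => positive by convention

    def test_too_few_focal_persons_rejected(self):
        p = GRMItemParams(1.0, (0.0,))
        with pytest.raises(ValueError, match="two focal persons"):
            essd(p, p, [0.0])


class TestDTF:
    def _items(self, rng, n_items=14):
        out = {}
        for j in range(n_items):
            b1 = rng.uniform(-2, 1)
            out[f"i{j}"] = GRMItemParams(rng.uniform(0.5, 3), (b1, b1 + rng.uniform(0.3, 1.5)))
        return out

    def test_no_dif_gives_zero(self):
        rng = np.random.default_rng(0)
        items = self._items(rng)
        out = dtf(items, dict(items), rng.normal(size=50))
        assert out.etsds == 0.0
        assert out.uetsds == 0.0
        assert out.etssd == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-1.0, 1.0))
    def test_unsigned_dominates_signed(self, seed, shift):
        rng = np.random.default_rng(seed)
        ref = self._items(rng, n_items=5)
        foc = {
            k: GRMItemParams(p.a, tuple(b + shift * rng.random() for b in p.b))
            for k, p in ref.items()
        }
        out = dtf(ref, foc, rng.normal(size=30))
        assert out.uetsds >= abs(out.etsds) - 1e-12

    def test_single_dif_item_diluted_at_scale_level(self):
        rng = np.random.default_rng(4)
        ref = self._items(rng)
        foc = dict(ref)
        foc["i3"] = GRMItemParams(ref["i3"].a, tuple(b + 0.8 for b in ref["i3"].b))
        thetas = rng.normal(size=400)
        item_es = essd(ref["i3"], foc["i3"], thetas).essd
        scale_es = dtf(ref, foc, thetas).etssd
        assert abs(scale_es) < abs(item_es)

    def test_empty_focal_sample_fatal(self):
        rng = np.random.default_rng(0)
        items = self._items(rng, 3)
        with pytest.raises(ValueError, match="empty"):
            dtf(items, dict(items), [])

    def test_location_equivariance(self):
        """Shifting all thetas and all thresholds together leaves ESSD unchanged."""
        rng = np.random.default_rng(8)
        ref = GRMItemParams(1.4, (-0.5, 0.6))
        foc = GRMItemParams(1.4, (0.1, 1.2))
        thetas = rng.normal(size=40)
        base = essd(ref, foc, thetas).essd
        c = 0.9
        ref_s = GRMItemParams(ref.a, tuple(b + c for b in ref.b))
        foc_s = GRMItemParams(foc.a, tuple(b + c for b in foc.b))
        shifted = essd(ref_s, foc_s, thetas + c).essd
        assert shifted == pytest.approx(base, abs=1e-10)


class TestPurification:
    def test_strong_dif_item_removed(self, grid):
        design = make_clinic_design(
            "race", "3", seed=13, n_reference=400, n_focal=400,
            a_range=(1.0, 2.5),
            planted_dif=[PlantedDIF("repetitive_interest", "uniform", 1.2)],
        )
        ds, _, group = simulate_dataset(design)
        anchors = purify_anchors(ds, group, grid)
        assert "repetitive_interest" not in anchors
        assert len(anchors) >= 10

    def test_null_data_keeps_full_anchor_set(self, grid, small_dataset):
        ds, _, group = small_dataset
        anchors = purify_anchors(ds, group, grid)
        # with the R2 >= 0.02 magnitude screen, chance flags are very rare
        assert len(anchors) >= 13

    def test_too_few_items_rejected(self, grid):
        with pytest.raises(ValueError, match="3 items"):
            purify_anchors(np.zeros((50, 2), int), np.repeat([0, 1], 25), grid)


class TestIRTLR:
    def _run_reps(self, n_reps, shift, seed):
        ss = np.random.SeedSequence(seed).generate_state(n_reps)
        settings_em = EMSettings(compute_se=False)
        grid = QuadratureGrid.normal()
        anchors = ["eye_contact", "gaze", "facial_expressions",
                   "vocalization", "shared_enjoyment"]
        pvals = []
        for s in ss:
            rep_seed = int(s % (2**31 - 1))
            planted = [PlantedDIF("repetitive_interest", "uniform", shift)] if shift else []
            design = make_clinic_design(
                "race", "3", seed=rep_seed, n_reference=500, n_focal=500,
                a_range=(1.0, 2.5), planted_dif=planted,
            )
            ds, _, group = simulate_dataset(design)
            out = irt_lr_dif(ds, group, "repetitive_interest", anchors,
                             grid, settings_em)
            assert out["chi2_total"] >= 0.0
            assert out["chi2_b"] >= 0.0
            pvals.append(out["p_total"])
        return np.array(pvals)

    def test_null_rejection_near_alpha(self):
        pvals = self._run_reps(30, shift=0.0, seed=101)
        rate = np.mean(pvals < 0.05)
        assert rate <= 0.2  # binomial band around alpha at 30 replicates

    def test_power_under_planted_shift(self):
        pvals = self._run_reps(15, shift=0.6, seed=202)
        assert np.mean(pvals < 0.05) >= 0.8

    def test_empty_anchor_set_rejected(self, small_dataset):
        ds, _, group = small_dataset
        with pytest.raises(ValueError, match="anchor"):
            irt_lr_dif(ds, group, "gaze", [])
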