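"""Monte-Carlo calibration studies for the DIF machinery.

These are the package's own operating-characteristic experiments: type-I
error and effect-size behavior of the uniform-DIF likelihood-ratio test
under no DIF, power and effect-size direction under planted uniform DIF,
and structure recovery of the dimensionality comparison.  Each replicate
runs the same code path as the analysis pipeline: simulate a two-group
dataset, calibrate the pooled GRM, score EAP traits, run the
ordinal-regression battery on the studied item, and (for effect sizes)
refit a multi-group model with all other items anchored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dif as dif_mod
from . import grm as grm_mod
from . import synthetic as syn
from .dimensionality import compare_models, fit_factor_model

__all__ = [
    "DIFStudyResult",
    "dif_replicate_study",
    "dimensionality_recovery_study",
    "parameter_recovery",
]

STUDIED_ITEM = "repetitive_interest"


@dataclass
class DIFStudyResult:
    """Per-replicate outcomes of a DIF simulation study."""

    p_uniform: np.ndarray
    p_total: np.ndarray
    r2_delta_uniform: np.ndarray
    delta_beta_pct: np.ndarray
    essd: np.ndarray
    etsds: np.ndarray
    uetsds: np.ndarray
    etssd: np.ndarray
    n_replicates: int = 0
    n_failed: int = 0

    @property
    def rejection_rate(self) -> float:
        ok = np.isfinite(self.p_uniform)
        return float(np.mean(self.p_uniform[ok] < 0.05))


def dif_replicate_study(
    n_replicates: int,
    seed: int,
    dif_shift: float = 0.0,
    n_per_group: int = 500,
    a_range: tuple[float, float] = (1.0, 2.5),
    compute_effect_sizes: bool = True,
    algorithm_id: str = "3",
) -> DIFStudyResult:
    """Replicated uniform-DIF experiment on one studied RRB item.

    ``dif_shift`` = 0 gives the null (type-I / effect-size calibration)
    study; a positive shift plants uniform DIF with higher focal difficulty.
    Item discriminations are drawn from ``a_range``; thresholds from the
    generator's defaults.  One studied item per replicate keeps replicates
    independent.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates * 2).reshape(n_replicates, 2)
    grid = grm_mod.QuadratureGrid.normal()
    settings = grm_mod.EMSettings(compute_se=False)
    planted = (
        (syn.PlantedDIF(STUDIED_ITEM, "uniform", dif_shift),) if dif_shift != 0 else ()
    )

    cols = {k: np.full(n_replicates, np.nan) for k in
            ("p_uniform", "p_total", "r2_delta_uniform", "delta_beta_pct",
             "essd", "etsds", "uetsds", "etssd")}
    n_failed = 0
    for rep in range(n_replicates):
        design_seed = int(rep_seeds[rep, 0] % (2**31 - 1))
        data_seed = int(rep_seeds[rep, 1] % (2**31 - 1))
        design = syn.make_clinic_design(
            "race", algorithm_id,
            planted_dif=planted,
            seed=design_seed,
            n_reference=n_per_group, n_focal=n_per_group,
            a_range=a_range,
        )
        ds, _, group = syn.simulate_dataset(design, np.random.default_rng(data_seed))
        pooled = grm_mod.fit_grm(ds, grid, settings)
        if STUDIED_ITEM not in pooled.params:
            n_failed += 1
            continue
        theta = grm_mod.eap_scores(ds, pooled, grid).eap
        j = list(design.spec.item_names).index(STUDIED_ITEM)
        res = dif_mod.analyze_item(STUDIED_ITEM, ds.responses[:, j], theta, group)
        if not res.converged:
            n_failed += 1
            continue
        cols["p_uniform"][rep] = res.p_uniform
        cols["p_total"][rep] = res.p_total
        cols["r2_delta_uniform"][rep] = res.r2_delta_uniform
        cols["delta_beta_pct"][rep] = res.delta_beta_pct

        if compute_effect_sizes:
            anchors = [i for i in design.spec.item_names if i != STUDIED_ITEM]
            mg = grm_mod.fit_multigroup_grm(
                ds, group, anchor_items=anchors, free_items=[STUDIED_ITEM],
                grid=grid, settings=settings,
            )
            ref_p = mg.group_params["reference"]
            foc_p = mg.group_params["focal"]
            focal_theta = theta[group == 1]
            es = dif_mod.essd(ref_p[STUDIED_ITEM], foc_p[STUDIED_ITEM],
                              focal_theta, STUDIED_ITEM)
            tes = dif_mod.dtf(ref_p, foc_p, focal_theta)
            cols["essd"][rep] = es.essd
            cols["etsds"][rep] = tes.etsds
            cols["uetsds"][rep] = tes.uetsds
            cols["etssd"][rep] = tes.etssd

    return DIFStudyResult(
        p_uniform=cols["p_uniform"],
        p_total=cols["p_total"],
        r2_delta_uniform=cols["r2_delta_uniform"],
        delta_beta_pct=cols["delta_beta_pct"],
        essd=cols["essd"],
        etsds=cols["etsds"],
        uetsds=cols["uetsds"],
        etssd=cols["etssd"],
        n_replicates=n_replicates,
        n_failed=n_failed,
    )


def dimensionality_recovery_study(
    n_replicates: int,
    seed: int,
    n_persons: int = 400,
    factor_corr: float = 0.5,
    algorithm_id: str = "3",
) -> dict[str, float]:
    """Structure recovery rates of the one- vs two-factor comparison.

    Half the experiment generates from a unidimensional GRM, half from a
    correlated two-factor GRM; each dataset is fitted under both structures
    and the preferred structure recorded.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates * 2).reshape(n_replicates, 2)
    n_half = n_persons // 2
    uni_correct = 0
    two_correct = 0
    for rep in range(n_replicates):
        s0 = int(rep_seeds[rep, 0] % (2**31 - 1))
        s1 = int(rep_seeds[rep, 1] % (2**31 - 1))
        design = syn.make_clinic_design(
            "race", algorithm_id, seed=s0,
            n_reference=n_half, n_focal=n_persons - n_half,
            a_range=(1.0, 2.5),
        )
        ds_uni, _, _ = syn.simulate_dataset(design, np.random.default_rng(s1))
        f1 = fit_factor_model(ds_uni, "unidimensional")
        f2 = fit_factor_model(ds_uni, "two_factor")
        if compare_models(f1, f2)["preferred"] == "unidimensional":
            uni_correct += 1
        ds_two = syn.simulate_two_factor_dataset(
            design, factor_corr=factor_corr, rng=np.random.default_rng(s1 + 1)
        )
        g1 = fit_factor_model(ds_two, "unidimensional")
        g2 = fit_factor_model(ds_two, "two_factor")
        if compare_models(g1, g2)["preferred"] == "two_factor":
            two_correct += 1
    return {
        "one_factor_recovery_rate": uni_correct / n_replicates,
        "two_factor_recovery_rate": two_correct / n_replicates,
        "n_replicates": n_replicates,
    }


def parameter_recovery(
    seed: int,
    n_persons: int = 3000,
    algorithm_id: str = "3",
) -> dict[str, float]:
    """Single large-sample calibration against generating truth (RMSE)."""
    design = syn.make_clinic_design(
        "race", algorithm_id, seed=seed,
        n_reference=n_persons // 2, n_focal=n_persons - n_persons // 2,
    )
    ds, thetas, _ = syn.simulate_dataset(design)
    grid = grm_mod.QuadratureGrid.normal()
    fit = grm_mod.fit_grm(ds, grid, grm_mod.EMSettings(compute_se=False))
    items = [i for i in design.spec.item_names if i in fit.params]
    true_a = np.array([design.ref_params[i].a for i in items])
    est_a = np.array([fit.params[i].a for i in items])
    true_b = np.concatenate([design.ref_params[i].b for i in items])
    est_b = np.concatenate([fit.params[i].b for i in items])
    eap = grm_mod.eap_scores(ds, fit, grid).eap
    return {
        "rmse_a": float(np.sqrt(np.mean((true_a - est_a) ** 2))),
        "rmse_b": float(np.sqrt(np.mean((true_b - est_b) ** 2))),
        "eap_correlation": float(np.corrcoef(eap, thetas)[0, 1]),
        "n_persons": n_persons,
    }
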