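"""End-to-end analysis orchestration.

One run = load (or simulate) -> recode -> complete-case filter -> per
comparison: subset, descriptive table, dimensionality check, pooled GRM
calibration, EAP scoring, per-item DIF battery, multi-group calibration of
flagged items, expected-score effect sizes and DTF, report tables and ICC
curve exports.  Every threshold, seed and recode count is written to a
structured JSON-lines run log, and output tables are rendered with fixed
formatting so identical configurations produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_model as dm
from . import dif as dif_mod
from . import grm as grm_mod
from . import synthetic as syn
from .dimensionality import compare_models, fit_factor_model

logger = logging.getLogger(__name__)

__all__ = [
    "Comparison",
    "AnalysisConfig",
    "RunReport",
    "count_planned_tests",
    "run_analysis",
    "render_dif_table",
    "render_icc_bundle",
]

DIF_TABLE_COLUMNS = [
    "item",
    "construct",
    "group",
    "a",
    "b1",
    "b2",
    "dif_type",
    "r2",
    "delta_beta",
    "essd",
    "etssd",
    "uetsds",
    "p_total",
    "significant",
]


@dataclass(frozen=True)
class Comparison:
    variable: str
    reference: str
    focal: str


@dataclass
class AnalysisConfig:
    """Everything one analysis run depends on."""

    input_path: str | None = None
    simulate: bool = True
    comparisons: list[Comparison] = field(
        default_factory=lambda: [
            Comparison("race", "White", "Black/African American"),
            Comparison("sex", "male", "female"),
        ]
    )
    algorithms: list[str] = field(default_factory=lambda: list(dm.ALGORITHM_IDS))
    flags: dif_mod.MagnitudeFlags = field(default_factory=dif_mod.MagnitudeFlags)
    engine: str = "olr"  # "olr" | "irt_lr" | "both"
    purify: bool = False
    run_dimensionality: bool = True
    exclude_ethnicity: bool = True
    planted_dif: list[syn.PlantedDIF] = field(default_factory=list)
    impact_mean: float = 0.0
    impact_sd: float = 1.0
    seed: int = 0
    output_dir: str | None = None
    n_quadrature: int = 49
    min_group_size: int = 50

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "comparisons" in raw:
            raw["comparisons"] = [Comparison(**c) for c in raw["comparisons"]]
        if "flags" in raw:
            raw["flags"] = dif_mod.MagnitudeFlags(**raw["flags"])
        if "planted_dif" in raw:
            raw["planted_dif"] = [syn.PlantedDIF(**d) for d in raw["planted_dif"]]
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All artifacts of one analysis run, keyed by (algorithm, comparison)."""

    config_digest: str
    seed: int
    dif_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    dtf_summaries: dict[tuple[str, str], dict] = field(default_factory=dict)
    dimensionality: dict[tuple[str, str], dict] = field(default_factory=dict)
    descriptives: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    icc_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    tests_planned: int = 0
    tests_run: int = 0
    tests_significant: int = 0
    log_records: list[dict] = field(default_factory=list)

    def log(self, **record) -> None:
        self.log_records.append(record)


def count_planned_tests(config: AnalysisConfig, n_items: int = 14) -> int:
    """Item-level DIF analyses the configuration implies."""
    return n_items * len(config.algorithms) * len(config.comparisons)


def _format_table(df: pd.DataFrame) -> str:
    """Deterministic TSV rendering (fixed float format)."""
    return df.to_csv(sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _analysis_dataset(config: AnalysisConfig, algorithm: str, comparison: Comparison,
                      seed: int):
    if config.simulate or config.input_path is None:
        design = syn.make_clinic_design(
            comparison.variable,
            algorithm,
            planted_dif=tuple(config.planted_dif),
            impact_mean=config.impact_mean,
            impact_sd=config.impact_sd,
            seed=seed,
        )
        ds, _, _ = syn.simulate_dataset(design)
        return ds
    spec = dm.algorithm_spec(algorithm)
    ds = dm.load_responses(config.input_path, spec)
    keep = ds.group_labels["algorithm"].astype(str).str.strip() == algorithm
    ds = dm.ResponseDataset(
        responses=ds.responses[keep.to_numpy()],
        spec=spec,
        person_ids=ds.person_ids[keep.to_numpy()],
        group_labels=ds.group_labels.loc[keep.to_numpy()].reset_index(drop=True),
        ethnicity_flag=ds.ethnicity_flag[keep.to_numpy()] if ds.ethnicity_flag is not None else None,
    )
    ds = dm.apply_recodes(ds)
    return dm.complete_case_filter(ds)


def _dif_row(item, construct, group_name, params, res, es, etssd, uetsds,
             significant):
    b = list(params.b) + [np.nan] * (2 - len(params.b))
    return {
        "item": item,
        "construct": construct,
        "group": group_name,
        "a": params.a,
        "b1": b[0],
        "b2": b[1],
        "dif_type": res.dif_type if res is not None else "none",
        "r2": res.r2_delta_total if res is not None else np.nan,
        "delta_beta": res.delta_beta_pct if res is not None else np.nan,
        "essd": es,
        "etssd": etssd,
        "uetsds": uetsds,
        "p_total": res.p_total if res is not None else np.nan,
        "significant": significant,
    }


def run_analysis(config: AnalysisConfig) -> RunReport:
    """Execute the full DIF pipeline for every algorithm x comparison cell."""
    report = RunReport(config_digest=config.digest(), seed=config.seed)
    report.log(event="start", config_digest=config.digest(), seed=config.seed,
               thresholds=config.flags.as_dict(), engine=config.engine)
    grid = grm_mod.QuadratureGrid.normal(config.n_quadrature)
    n_items = 14
    report.tests_planned = count_planned_tests(config, n_items)
    ss = np.random.SeedSequence(config.seed)
    cell_seeds = ss.generate_state(len(config.algorithms) * len(config.comparisons))

    cell = 0
    for algorithm in config.algorithms:
        for comparison in config.comparisons:
            seed = int(cell_seeds[cell] % (2**31 - 1))
            cell += 1
            key = (algorithm, comparison.variable)
            try:
                ds = _analysis_dataset(config, algorithm, comparison, seed)
                ds = dm.subset_comparison(
                    ds,
                    comparison.variable,
                    comparison.reference,
                    comparison.focal,
                    exclude_ethnicity=config.exclude_ethnicity,
                    min_group_size=config.min_group_size,
                )
            except ValueError as exc:
                report.log(event="cell_failed", algorithm=algorithm,
                           comparison=comparison.variable, stage="data", error=str(exc))
                raise RuntimeError(
                    f"stage 'data' failed for algorithm {algorithm}, "
                    f"comparison {comparison.variable}: {exc}"
                ) from exc

            group = dm.group_indicator(ds, comparison.variable, comparison.focal)
            report.descriptives[key] = dm.describe_items(ds, comparison.variable)

            if config.run_dimensionality:
                f_uni = fit_factor_model(ds, "unidimensional", grid)
                f_two = fit_factor_model(ds, "two_factor", grid)
                cmp_res = compare_models(f_uni, f_two)
                report.dimensionality[key] = {
                    "preferred": cmp_res["preferred"],
                    "unidimensional": {
                        "discrepancy": f_uni.discrepancy, "df": f_uni.df,
                        "cfi": f_uni.cfi, "tli": f_uni.tli,
                        "rmsea": f_uni.rmsea, "srmr": f_uni.srmr,
                    },
                    "two_factor": {
                        "discrepancy": f_two.discrepancy, "df": f_two.df,
                        "cfi": f_two.cfi, "tli": f_two.tli,
                        "rmsea": f_two.rmsea, "srmr": f_two.srmr,
                        "factor_corr": f_two.factor_corr,
                    },
                }
                report.log(event="dimensionality", algorithm=algorithm,
                           comparison=comparison.variable,
                           preferred=cmp_res["preferred"])

            settings = grm_mod.EMSettings(compute_se=False)
            pooled = grm_mod.fit_grm(ds, grid, settings)
            theta = grm_mod.eap_scores(ds, pooled, grid).eap
            names = [n for n in ds.spec.item_names if n in pooled.params]

            if config.purify:
                anchors0 = dif_mod.purify_anchors(ds, group, grid, config.flags, settings)
            else:
                anchors0 = list(names)

            results: dict[str, dif_mod.DIFResult] = {}
            for j, item in enumerate(ds.spec.item_names):
                if item not in pooled.params:
                    continue
                res = dif_mod.analyze_item(
                    item, ds.responses[:, j], theta, group, config.flags.alpha
                )
                if config.engine in ("irt_lr", "both"):
                    anc = [a for a in anchors0 if a != item] or [
                        n for n in names if n != item
                    ]
                    irt = dif_mod.irt_lr_dif(ds, group, item, anc, grid, settings)
                    olr_sig = res.converged and res.p_total < config.flags.alpha
                    irt_sig = irt["p_total"] < config.flags.alpha
                    if config.engine == "irt_lr":
                        res.p_total = irt["p_total"]
                        res.chi2_total = irt["chi2_total"]
                        res.p_uniform = irt["p_b"]
                        res.chi2_uniform = irt["chi2_b"]
                        res.p_nonuniform = irt["p_a_given_b"]
                        res.chi2_nonuniform = irt["chi2_a_given_b"]
                        res.dif_type = dif_mod.classify_dif(
                            res.p_uniform, res.p_nonuniform, config.flags.alpha
                        )
                    elif olr_sig != irt_sig:
                        report.log(event="engine_disagreement", algorithm=algorithm,
                                   comparison=comparison.variable, item=item,
                                   olr_p=res.p_total, irt_p=irt["p_total"])
                results[item] = res
                report.tests_run += 1

            flagged = [
                i for i, r in results.items()
                if r.converged and r.p_total < config.flags.alpha
            ]
            report.tests_significant += len(flagged)
            report.log(event="dif_tests", algorithm=algorithm,
                       comparison=comparison.variable,
                       flagged=flagged, n_run=len(results))

            anchors = [n for n in names if n not in flagged]
            if not anchors:  # everything flagged: fall back to least-significant item
                anchors = [max(results, key=lambda i: results[i].p_total)]
            focal_mask = group == 1
            if flagged:
                mg = grm_mod.fit_multigroup_grm(
                    ds, group, anchor_items=anchors, free_items=flagged,
                    grid=grid, settings=settings,
                )
                ref_p = mg.group_params["reference"]
                foc_p = mg.group_params["focal"]
            else:
                ref_p = dict(pooled.params)
                foc_p = dict(pooled.params)
            focal_theta = theta[focal_mask]
            test_es = dif_mod.dtf(ref_p, foc_p, focal_theta)
            report.dtf_summaries[key] = {
                "etsds": test_es.etsds,
                "uetsds": test_es.uetsds,
                "etssd": test_es.etssd,
                "etssd_meaningful": bool(abs(test_es.etssd) >= config.flags.etssd_cutoff),
                "uetsds_meaningful": bool(test_es.uetsds > config.flags.uetsds_cutoff),
            }

            rows = []
            for item in names:
                res = results.get(item)
                construct = ds.spec.construct_map[item]
                if item in flagged:
                    es = dif_mod.essd(ref_p[item], foc_p[item], focal_theta, item).essd
                else:
                    es = 0.0
                sig = item in flagged
                rows.append(_dif_row(item, construct, comparison.reference,
                                     ref_p[item], res, es,
                                     test_es.etssd, test_es.uetsds, sig))
                rows.append(_dif_row(item, construct, comparison.focal,
                                     foc_p[item], res, es,
                                     test_es.etssd, test_es.uetsds, sig))
            report.dif_tables[key] = pd.DataFrame(rows, columns=DIF_TABLE_COLUMNS)

            if flagged:
                theta_grid = np.linspace(-4, 4, 81)
                icc = grm_mod.tabulate_icc(
                    {
                        comparison.reference: {i: ref_p[i] for i in flagged},
                        comparison.focal: {i: foc_p[i] for i in flagged},
                    },
                    theta_grid,
                )
                report.icc_tables[key] = icc

    report.log(event="done", planned=report.tests_planned,
               run=report.tests_run, significant=report.tests_significant)
    if config.output_dir:
        _write_artifacts(report, config)
    return report


def _write_artifacts(report: RunReport, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (alg, var), df in report.dif_tables.items():
        stem = f"dif_{alg.replace('.', '_')}_{var}"
        (out / f"{stem}.tsv").write_text(_format_table(df))
    for (alg, var), df in report.descriptives.items():
        stem = f"describe_{alg.replace('.', '_')}_{var}"
        (out / f"{stem}.tsv").write_text(_format_table(df))
    summary = {
        "config_digest": report.config_digest,
        "seed": report.seed,
        "tests_planned": report.tests_planned,
        "tests_run": report.tests_run,
        "tests_significant": report.tests_significant,
        "dtf": {f"{a}|{v}": d for (a, v), d in report.dtf_summaries.items()},
        "dimensionality": {f"{a}|{v}": d for (a, v), d in report.dimensionality.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    with open(out / "run_log.jsonl", "w") as fh:
        for rec in report.log_records:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
    render_icc_bundle(report, out / "icc")


def render_dif_table(report: RunReport, algorithm: str, comparison_variable: str,
                     emit_all: bool = False) -> pd.DataFrame:
    """Suspected-DIF table: two rows (reference, focal) per significant item.

    With ``emit_all``, every item appears regardless of significance.
    """
    df = report.dif_tables[(algorithm, comparison_variable)]
    if emit_all:
        return df.copy()
    return df.loc[df["significant"]].reset_index(drop=True)


def render_icc_bundle(report: RunReport, outdir) -> list[Path]:
    """One characteristic-curve TSV per flagged item, both groups side by side."""
    outdir = Path(outdir)
    written: list[Path] = []
    any_curves = False
    for (alg, var), icc in report.icc_tables.items():
        any_curves = True
        outdir.mkdir(parents=True, exist_ok=True)
        for item, sub in icc.groupby("item", sort=True):
            path = outdir / f"icc_{alg.replace('.', '_')}_{var}_{item}.tsv"
            path.write_text(_format_table(sub.reset_index(drop=True)))
            written.append(path)
    if not any_curves:
        logger.info("no flagged items: empty ICC bundle")
    return written
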