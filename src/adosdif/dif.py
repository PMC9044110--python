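"""Differential item functioning detection and effect-size grading.

Two detection engines are provided.

1. **Ordinal-regression nested models** (primary).  For each item, three
   proportional-odds logistic models are fitted on the EAP trait estimate:

   - M1: item ~ theta
   - M2: item ~ theta + group
   - M3: item ~ theta + group + theta x group

   Likelihood-ratio chi-square tests compare M2 vs M1 (uniform DIF, df=1),
   M3 vs M2 (nonuniform DIF, df=1) and M3 vs M1 (total, df=2).  Magnitude is
   graded by McFadden pseudo-R-squared changes between nested models (cutoff
   0.02), by the relative change in the theta coefficient when the group
   term enters (delta-beta, 10% cutoff), and by the expected standardized
   score difference (ESSD, Cohen's-d metric).

2. **Anchored IRT likelihood-ratio tests**.  Multi-group GRM fits compare a
   fully constrained studied item against threshold-free and fully free
   versions, with anchor items linking the group scales.

Scale-level differential test functioning (DTF) aggregates per-person
expected-total-score differences over the focal sample: ETSDS (signed mean),
UETSDS (mean absolute, in raw scale points) and ETSSD (standardized).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .grm import (
    EMSettings,
    GRMItemParams,
    QuadratureGrid,
    eap_scores,
    expected_item_score,
    expected_test_score,
    fit_grm,
    fit_multigroup_grm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OLRModelTriple",
    "DIFResult",
    "ItemEffectSize",
    "TestEffectSize",
    "MagnitudeFlags",
    "fit_olr_triple",
    "lr_tests",
    "pseudo_r2_delta",
    "delta_beta",
    "classify_dif",
    "analyze_item",
    "essd",
    "dtf",
    "purify_anchors",
    "irt_lr_dif",
]


@dataclass
class OLRModelTriple:
    """Log-likelihoods and theta/group coefficients of the three nested fits."""

    ll_m1: float
    ll_m2: float
    ll_m3: float
    ll_null: float
    beta_theta_m1: float
    beta_theta_m2: float
    beta_group_m2: float
    converged: bool = True

    def __post_init__(self) -> None:
        # nested maximum likelihoods must be ordered (up to optimizer noise)
        if self.ll_m2 < self.ll_m1 - 1e-6 or self.ll_m3 < self.ll_m2 - 1e-6:
            self.converged = False


@dataclass
class DIFResult:
    """Per-item DIF test battery."""

    item: str
    chi2_uniform: float
    chi2_nonuniform: float
    chi2_total: float
    p_uniform: float
    p_nonuniform: float
    p_total: float
    r2_delta_uniform: float
    r2_delta_nonuniform: float
    r2_delta_total: float
    delta_beta_pct: float
    dif_type: str = "none"
    converged: bool = True


@dataclass
class ItemEffectSize:
    item: str
    essd: float


@dataclass
class TestEffectSize:
    etsds: float
    uetsds: float
    etssd: float


@dataclass(frozen=True)
class MagnitudeFlags:
    """Significance level and magnitude cutoffs used to grade DIF."""

    alpha: float = 0.05
    r2_cutoff: float = 0.02
    delta_beta_cutoff_pct: float = 10.0
    etssd_cutoff: float = 0.2
    uetsds_cutoff: float = 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "r2_cutoff": self.r2_cutoff,
            "delta_beta_cutoff_pct": self.delta_beta_cutoff_pct,
            "etssd_cutoff": self.etssd_cutoff,
            "uetsds_cutoff": self.uetsds_cutoff,
        }


# ---------------------------------------------------------------------------
# ordinal-regression engine


def _null_log_likelihood(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def fit_olr_triple(y, theta, group) -> OLRModelTriple:
    """Fit the M1/M2/M3 proportional-odds triple by maximum likelihood.

    Larger models are warm-started from the smaller model's solution so the
    nesting inequality ll(M1) <= ll(M2) <= ll(M3) holds numerically.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = np.asarray(y)
    theta = np.asarray(theta, dtype=float)
    group = np.asarray(group, dtype=float)
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("item has fewer than 2 observed categories")
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be present")
    # contiguous recode for the ordered model
    y = np.searchsorted(cats, y)
    n_cut = len(cats) - 1

    x1 = theta[:, None]
    x2 = np.column_stack([theta, group])
    x3 = np.column_stack([theta, group, theta * group])

    def _fit(x, start=None):
        model = OrderedModel(y, x, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(
                    method="bfgs", maxiter=200, disp=False, start_params=start
                )
            except Exception:
                res = model.fit(method="nm", maxiter=2000, disp=False)
        return res

    m1 = _fit(x1)
    s2 = np.concatenate([m1.params[:1], [0.0], m1.params[1:]])
    m2 = _fit(x2, s2)
    if m2.llf < m1.llf:
        m2_alt = _fit(x2)
        if m2_alt.llf > m2.llf:
            m2 = m2_alt
    s3 = np.concatenate([m2.params[:2], [0.0], m2.params[2:]])
    m3 = _fit(x3, s3)
    if m3.llf < m2.llf:
        m3_alt = _fit(x3)
        if m3_alt.llf > m3.llf:
            m3 = m3_alt

    converged = all(
        getattr(m, "mle_retvals", {}).get("converged", True) for m in (m1, m2, m3)
    ) and np.isfinite([m1.llf, m2.llf, m3.llf]).all()
    return OLRModelTriple(
        ll_m1=float(m1.llf),
        ll_m2=float(m2.llf),
        ll_m3=float(m3.llf),
        ll_null=_null_log_likelihood(y),
        beta_theta_m1=float(m1.params[0]),
        beta_theta_m2=float(m2.params[0]),
        beta_group_m2=float(m2.params[1]),
        converged=converged,
    )


def lr_tests(triple: OLRModelTriple) -> dict[str, float]:
    """Likelihood-ratio chi-squares and p-values for the three contrasts."""
    pairs = {
        "uniform": (triple.ll_m2, triple.ll_m1, 1),
        "nonuniform": (triple.ll_m3, triple.ll_m2, 1),
        "total": (triple.ll_m3, triple.ll_m1, 2),
    }
    out: dict[str, float] = {}
    for name, (big, small, df) in pairs.items():
        stat = 2.0 * (big - small)
        if stat < -1e-6:
            raise RuntimeError(
                f"negative LR statistic for {name} contrast ({stat:.3g}): optimizer failure"
            )
        stat = max(stat, 0.0)
        out[f"chi2_{name}"] = stat
        out[f"p_{name}"] = float(chi2.sf(stat, df))
    return out


def pseudo_r2_delta(triple: OLRModelTriple) -> dict[str, float]:
    """McFadden pseudo-R-squared differences between the nested models."""
    if triple.ll_null >= -1e-12:
        raise ValueError("degenerate constant item: null log-likelihood is zero")
    r2 = {m: 1.0 - ll / triple.ll_null for m, ll in
          (("m1", triple.ll_m1), ("m2", triple.ll_m2), ("m3", triple.ll_m3))}
    return {
        "uniform": max(r2["m2"] - r2["m1"], 0.0),
        "nonuniform": max(r2["m3"] - r2["m2"], 0.0),
        "total": max(r2["m3"] - r2["m1"], 0.0),
    }


def delta_beta(triple: OLRModelTriple) -> float:
    """Relative change (%) of the theta coefficient when group enters (M1 vs M2).

    Undefined (NaN) when the M1 theta coefficient is numerically zero.
    """
    if abs(triple.beta_theta_m1) < 1e-8:
        warnings.warn("theta coefficient of M1 is ~0; delta-beta undefined")
        return float("nan")
    return 100.0 * abs(triple.beta_theta_m2 - triple.beta_theta_m1) / abs(triple.beta_theta_m1)


def classify_dif(p_uniform: float, p_nonuniform: float, alpha: float = 0.05) -> str:
    """DIF label from the two single-df contrasts.

    A significant interaction wins (nonuniform) because a trait-by-group
    interaction invalidates a pure threshold-shift description; otherwise a
    significant group main effect is uniform DIF; otherwise none.
    """
    if p_nonuniform < alpha:
        return "nonuniform"
    if p_uniform < alpha:
        return "uniform"
    return "none"


def analyze_item(item: str, y, theta, group, alpha: float = 0.05) -> DIFResult:
    """Full ordinal-regression DIF battery for one item."""
    try:
        triple = fit_olr_triple(y, theta, group)
        tests = lr_tests(triple)
        r2 = pseudo_r2_delta(triple)
        db = delta_beta(triple)
    except (ValueError, RuntimeError) as exc:
        logger.warning("item %s: DIF fit failed (%s)", item, exc)
        nan = float("nan")
        return DIFResult(
            item=item,
            chi2_uniform=nan, chi2_nonuniform=nan, chi2_total=nan,
            p_uniform=nan, p_nonuniform=nan, p_total=nan,
            r2_delta_uniform=nan, r2_delta_nonuniform=nan, r2_delta_total=nan,
            delta_beta_pct=nan, dif_type="failed", converged=False,
        )
    return DIFResult(
        item=item,
        chi2_uniform=tests["chi2_uniform"],
        chi2_nonuniform=tests["chi2_nonuniform"],
        chi2_total=tests["chi2_total"],
        p_uniform=tests["p_uniform"],
        p_nonuniform=tests["p_nonuniform"],
        p_total=tests["p_total"],
        r2_delta_uniform=r2["uniform"],
        r2_delta_nonuniform=r2["nonuniform"],
        r2_delta_total=r2["total"],
        delta_beta_pct=db,
        dif_type=classify_dif(tests["p_uniform"], tests["p_nonuniform"], alpha),
        converged=triple.converged,
    )


# ---------------------------------------------------------------------------
# expected-score effect sizes


def essd(
    ref_params: GRMItemParams,
    focal_params: GRMItemParams,
    focal_thetas,
    item: str = "",
) -> ItemEffectSize:
    """Expected standardized score difference (Cohen's-d metric).

    Mean over the focal sample of reference-minus-focal expected item scores,
    divided by the pooled SD (root mean of the two ddof=1 variances) of the
    two expected-score vectors.  Positive ESSD means the item is harder for
    the focal group (underestimation of severity at equal theta).
    """
    if ref_params.n_categories != focal_params.n_categories:
        raise ValueError("category counts differ between groups")
    th = np.asarray(focal_thetas, dtype=float)
    if th.size < 2:
        raise ValueError("at least two focal persons are required")
    e_ref = np.asarray(expected_item_score(ref_params, th))
    e_foc = np.asarray(expected_item_score(focal_params, th))
    diff = float(np.mean(e_ref - e_foc))
    pooled = float(np.sqrt((e_ref.var(ddof=1) + e_foc.var(ddof=1)) / 2.0))
    if pooled < 1e-12:
        if abs(diff) < 1e-12:
            return ItemEffectSize(item=item, essd=0.0)
        warnings.warn(f"item {item!r}: zero pooled SD, ESSD undefined")
        return ItemEffectSize(item=item, essd=float("nan"))
    return ItemEffectSize(item=item, essd=diff / pooled)


def dtf(
    ref_params: dict[str, GRMItemParams],
    focal_params: dict[str, GRMItemParams],
    focal_thetas,
) -> TestEffectSize:
    """Differential test functioning over the focal sample.

    Per focal person, the expected total score under reference parameters
    minus under focal parameters; ETSDS is the signed mean, UETSDS the mean
    of absolute values (raw scale points), ETSSD the standardized mean.
    """
    if set(ref_params) != set(focal_params):
        raise ValueError("item sets differ between groups")
    th = np.asarray(focal_thetas, dtype=float)
    if th.size == 0:
        raise ValueError("empty focal sample")
    items = sorted(ref_params)
    ets_ref = np.asarray(expected_test_score([ref_params[i] for i in items], th))
    ets_foc = np.asarray(expected_test_score([focal_params[i] for i in items], th))
    diff = ets_ref - ets_foc
    etsds = float(diff.mean())
    uetsds = float(np.abs(diff).mean())
    pooled = float(np.sqrt((ets_ref.var(ddof=1) + ets_foc.var(ddof=1)) / 2.0))
    etssd = etsds / pooled if pooled > 1e-12 else 0.0
    return TestEffectSize(etsds=etsds, uetsds=uetsds, etssd=etssd)


# ---------------------------------------------------------------------------
# anchor purification and the IRT-LR engine


def purify_anchors(
    ds,
    group,
    grid: QuadratureGrid | None = None,
    flags: MagnitudeFlags | None = None,
    settings: EMSettings | None = None,
    max_rounds: int = 10,
) -> list[str]:
    """Iteratively remove DIF-flagged items from the anchor set.

    Each round scores theta from a pooled calibration of the current anchors,
    runs the ordinal-regression battery on every item, and drops items that
    are significant *and* pass the pseudo-R-squared magnitude screen.  Stops
    at a fixed point or after ``max_rounds``; if the candidate anchor set
    would become empty, the last non-empty set is kept with a warning.
    """
    from .grm import _response_matrix

    grid = grid or QuadratureGrid.normal()
    flags = flags or MagnitudeFlags()
    settings = settings or EMSettings(compute_se=False)
    x, names = _response_matrix(ds)
    if len(names) < 3:
        raise ValueError("at least 3 items are required for purification")
    group = np.asarray(group)
    anchors = list(names)
    for _ in range(max_rounds):
        cols = [names.index(n) for n in anchors]
        fit = fit_grm(x[:, cols], grid, settings)
        theta = eap_scores(x[:, cols], list(fit.params.values()), grid).eap
        flagged = []
        for j, name in enumerate(names):
            res = analyze_item(name, x[:, j], theta, group, flags.alpha)
            if (
                res.converged
                and res.p_total < flags.alpha
                and res.r2_delta_total >= flags.r2_cutoff
            ):
                flagged.append(name)
        new_anchors = [n for n in names if n not in flagged]
        if not new_anchors:
            warnings.warn("purification would empty the anchor set; keeping last set")
            return anchors
        if new_anchors == anchors:
            return anchors
        anchors = new_anchors
    return anchors


def irt_lr_dif(
    ds,
    group,
    item: str,
    anchors: list[str],
    grid: QuadratureGrid | None = None,
    settings: EMSettings | None = None,
) -> dict[str, float]:
    """Anchored IRT likelihood-ratio DIF tests for one studied item.

    Three nested multi-group GRM fits on the anchors plus the studied item:
    all parameters equal; thresholds free (df = K-1); discrimination and
    thresholds free (df = K).  Chi-squares are twice the log-likelihood gains.
    """
    from .grm import _response_matrix

    grid = grid or QuadratureGrid.normal()
    settings = settings or EMSettings(compute_se=False)
    if not anchors:
        raise ValueError("anchor set must be non-empty")
    if item in anchors:
        raise ValueError("the studied item cannot be its own anchor")
    x, names = _response_matrix(ds)
    cols = [names.index(n) for n in anchors] + [names.index(item)]
    sub = x[:, cols]
    sub_names = anchors + [item]
    k_item = int(x[:, names.index(item)].max()) + 1

    def _fit(constraint: str):
        return fit_multigroup_grm(
            sub,
            group,
            anchor_items=[f"item_{i + 1}" for i in range(len(anchors))],
            free_items=[f"item_{len(sub_names)}"],
            grid=grid,
            settings=settings,
            constraints={f"item_{len(sub_names)}": constraint},
        )

    fit_eq = _fit("equal")
    fit_b = _fit("b_free")
    fit_ab = _fit("free")
    ll_eq, ll_b, ll_ab = (
        fit_eq.log_likelihood,
        fit_b.log_likelihood,
        fit_ab.log_likelihood,
    )
    chi2_b = max(2.0 * (ll_b - ll_eq), 0.0)
    chi2_ab = max(2.0 * (ll_ab - ll_eq), 0.0)
    chi2_a_given_b = max(2.0 * (ll_ab - ll_b), 0.0)
    df_b = k_item - 1
    df_ab = k_item
    return {
        "chi2_b": chi2_b,
        "p_b": float(chi2.sf(chi2_b, df_b)),
        "chi2_total": chi2_ab,
        "p_total": float(chi2.sf(chi2_ab, df_ab)),
        "chi2_a_given_b": chi2_a_given_b,
        "p_a_given_b": float(chi2.sf(chi2_a_given_b, 1)),
        "converged": float(fit_eq.converged and fit_b.converged and fit_ab.converged),
    }
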