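"""Graded response model: probabilities, marginal-maximum-likelihood calibration,
multi-group estimation with anchor items, and EAP trait scoring.

The graded response model describes an ordinal item response :math:`X \\in
\\{0, \\dots, K-1\\}` through cumulative logistic curves

.. math::

    P(X \\ge k \\mid \\theta) = \\mathrm{logit}^{-1}\\bigl(a (\\theta - b_k)\\bigr),
    \\qquad k = 1, \\dots, K-1,

with a positive discrimination ``a`` and strictly increasing category
thresholds ``b_1 < \\dots < b_{K-1}`` on the latent-trait scale.  Category
probabilities are adjacent differences of the cumulative curves.  No 1.7
scaling constant is used; the logistic metric is taken as-is, matching the
convention of modern IRT software.

Calibration is marginal maximum likelihood: the latent trait is integrated
out over a fixed quadrature grid (default 49 equally spaced nodes on
[-6, 6] with standard-normal prior weights) and the item parameters are
updated by an EM algorithm whose M-step runs a batched Newton ascent with
step-halving on the expected complete-data log-likelihood.  Multi-group
calibration constrains anchor items equal across groups, frees the studied
items, fixes the reference latent distribution at N(0, 1) and estimates the
focal group's latent mean and SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, xlogy
from scipy.stats import norm

__all__ = [
    "GRMItemParams",
    "QuadratureGrid",
    "EMSettings",
    "GRMFit",
    "ThetaEstimates",
    "cumulative_probability",
    "category_probabilities",
    "expected_item_score",
    "expected_test_score",
    "marginal_log_likelihood",
    "fit_grm",
    "fit_multigroup_grm",
    "eap_scores",
    "tabulate_icc",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class GRMItemParams:
    """Discrimination ``a`` and ordered thresholds ``b`` of one item."""

    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"discrimination must be finite and positive, got {self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) < 1 or not all(np.isfinite(b)):
            raise ValueError(f"thresholds must be a non-empty finite sequence, got {b}")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {b}")
        object.__setattr__(self, "b", b)

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature nodes with positive prior weights summing to one."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-D arrays of equal length")
        if np.any(weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-8:
            raise ValueError("quadrature weights must sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def normal(
        cls,
        n_nodes: int = 49,
        bounds: tuple[float, float] = (-6.0, 6.0),
        mean: float = 0.0,
        sd: float = 1.0,
    ) -> "QuadratureGrid":
        """Equally spaced nodes with renormalized normal-density weights."""
        if not (np.isfinite(mean) and np.isfinite(sd) and sd > 0):
            raise ValueError("prior mean/sd must be finite with sd > 0")
        nodes = np.linspace(bounds[0], bounds[1], n_nodes)
        w = norm.pdf(nodes, loc=mean, scale=sd)
        return cls(nodes=nodes, weights=w / w.sum())

    def reweighted(self, mean: float, sd: float) -> "QuadratureGrid":
        """Same nodes, normal prior with the given mean and SD."""
        w = norm.pdf(self.nodes, loc=mean, scale=sd)
        return QuadratureGrid(nodes=self.nodes, weights=w / w.sum())


@dataclass
class EMSettings:
    """Convergence and inner-loop controls for the EM calibration."""

    max_iter: int = 500
    tol: float = 1e-4  # max absolute parameter change between cycles
    newton_steps: int = 3  # Newton ascent steps per item per M-step
    min_a: float = 1e-3
    compute_se: bool = True


@dataclass
class GRMFit:
    """Result of a marginal-maximum-likelihood calibration."""

    item_names: list[str]
    params: dict[str, GRMItemParams]
    log_likelihood: float
    standard_errors: dict[str, dict[str, float]]
    converged: bool
    n_iter: int
    max_change: float
    ll_trace: list[float] = field(default_factory=list)
    excluded_items: list[str] = field(default_factory=list)
    collapsed: dict[str, list[int]] = field(default_factory=dict)
    # multi-group extras
    group_params: dict[str, dict[str, GRMItemParams]] | None = None
    focal_mean: float | None = None
    focal_sd: float | None = None
    anchor_items: list[str] | None = None


@dataclass
class ThetaEstimates:
    """EAP trait estimates with posterior SDs, one per person."""

    eap: np.ndarray
    psd: np.ndarray


# ---------------------------------------------------------------------------
# closed-form curves


def cumulative_probability(params: GRMItemParams, k: int, theta) -> np.ndarray | float:
    """P(X >= k | theta) for category index k in 1..K-1."""
    if not 1 <= k <= len(params.b):
        raise ValueError(f"category index k={k} out of range 1..{len(params.b)}")
    theta = np.asarray(theta, dtype=float)
    out = expit(params.a * (theta - params.b[k - 1]))
    return float(out) if out.ndim == 0 else out


def category_probabilities(params: GRMItemParams, theta) -> np.ndarray:
    """Probability of each response category at theta; last axis sums to 1."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(params.b)
    cum = expit(params.a * (theta[..., None] - b))  # (..., K-1)
    upper = np.concatenate([np.ones_like(theta[..., None]), cum], axis=-1)
    lower = np.concatenate([cum, np.zeros_like(theta[..., None])], axis=-1)
    return upper - lower


def expected_item_score(params: GRMItemParams, theta) -> np.ndarray | float:
    """E[X | theta] = sum_k P(X >= k | theta); lies in [0, K-1]."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(params.b)
    out = expit(params.a * (theta[..., None] - b)).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def expected_test_score(items, theta) -> np.ndarray | float:
    """Expected total score: sum of expected item scores over the scale.

    ``items`` is an iterable of GRMItemParams (dict values are accepted).
    """
    if isinstance(items, dict):
        items = list(items.values())
    items = list(items)
    if not items:
        raise ValueError("at least one item is required")
    theta = np.asarray(theta, dtype=float)
    total = sum(np.asarray(expected_item_score(p, theta)) for p in items)
    return float(total) if np.ndim(total) == 0 else total


# ---------------------------------------------------------------------------
# internal array engine
#
# Items are held in padded arrays: a (J,), b (J, Mmax) with +inf padding for
# items with fewer thresholds.  expit(a * (theta - inf)) = 0, so padded
# cumulative curves vanish and padded categories get probability zero without
# masking the forward pass.


def _pack_params(params_list: list[GRMItemParams]) -> tuple[np.ndarray, np.ndarray]:
    mmax = max(len(p.b) for p in params_list)
    a = np.array([p.a for p in params_list], dtype=float)
    b = np.full((len(params_list), mmax), np.inf)
    for j, p in enumerate(params_list):
        b[j, : len(p.b)] = p.b
    return a, b


def _unpack_params(a: np.ndarray, b: np.ndarray) -> list[GRMItemParams]:
    out = []
    for j in range(len(a)):
        bj = b[j][np.isfinite(b[j])]
        out.append(GRMItemParams(a=float(a[j]), b=tuple(float(x) for x in bj)))
    return out


def _cat_prob_table(a: np.ndarray, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (J, Kmax, Q)."""
    valid = np.isfinite(b)
    z = a[:, None, None] * (nodes[None, None, :] - np.where(valid, b, 0.0)[:, :, None])
    z = np.where(valid[:, :, None], z, -np.inf)
    pstar = expit(z)  # (J, M, Q)
    j, m, q = pstar.shape
    upper = np.concatenate([np.ones((j, 1, q)), pstar], axis=1)
    lower = np.concatenate([pstar, np.zeros((j, 1, q))], axis=1)
    return upper - lower


def _estep(
    x: np.ndarray, a: np.ndarray, b: np.ndarray, nodes: np.ndarray, logw: np.ndarray
) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood and posterior node weights (n, Q)."""
    logp = np.log(np.clip(_cat_prob_table(a, b, nodes), _PROB_FLOOR, None))
    n = x.shape[0]
    logl = np.zeros((n, len(nodes)))
    for j in range(x.shape[1]):
        logl += logp[j, x[:, j], :]
    lj = logl + logw[None, :]
    m = lj.max(axis=1, keepdims=True)
    w = np.exp(lj - m)
    tot = w.sum(axis=1)
    ll = float(np.sum(np.log(tot) + m[:, 0]))
    return ll, w / tot[:, None]


def _expected_counts(x: np.ndarray, post: np.ndarray, kmax: int) -> np.ndarray:
    """Expected response counts r[j, q, c] from posterior node weights."""
    n, j_items = x.shape
    q = post.shape[1]
    r = np.zeros((j_items, q, kmax))
    for j in range(j_items):
        for c in range(kmax):
            mask = x[:, j] == c
            if mask.any():
                r[j, :, c] = post[mask].sum(axis=0)
    return r


def _q_and_grad(
    a: np.ndarray, b: np.ndarray, r: np.ndarray, nodes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected complete-data log-likelihood Q per item, with its gradient.

    Returns (Q (J,), g_a (J,), g_b (J, M)); padded threshold gradients are 0.
    """
    valid = np.isfinite(b)
    bf = np.where(valid, b, 0.0)
    z = a[:, None, None] * (nodes[None, None, :] - bf[:, :, None])
    z = np.where(valid[:, :, None], z, -np.inf)
    pstar = expit(z)
    s = pstar * (1.0 - pstar)  # d expit/dz; zero at padding
    jn, m, qn = pstar.shape
    upper = np.concatenate([np.ones((jn, 1, qn)), pstar], axis=1)
    lower = np.concatenate([pstar, np.zeros((jn, 1, qn))], axis=1)
    pcat = np.clip(upper - lower, _PROB_FLOOR, None)  # (J, K, Q)
    rt = np.swapaxes(r, 1, 2)  # (J, K, Q)
    qval = np.sum(xlogy(rt, pcat), axis=(1, 2))
    ratio = rt / pcat
    # dQ/dP*_k = r_k/P_k - r_{k-1}/P_{k-1}   (category k gains, k-1 loses)
    c = ratio[:, 1:, :] - ratio[:, :-1, :]  # (J, M, Q)
    cs = c * s
    theta_minus_b = np.where(valid[:, :, None], nodes[None, None, :] - bf[:, :, None], 0.0)
    g_a = np.sum(cs * theta_minus_b, axis=(1, 2))
    g_b = -a[:, None] * np.sum(cs, axis=2)
    g_b = np.where(valid, g_b, 0.0)
    return qval, g_a, g_b


def _mstep_newton(
    a: np.ndarray,
    b: np.ndarray,
    r: np.ndarray,
    nodes: np.ndarray,
    settings: EMSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Newton ascent with step-halving on Q; monotone by construction."""
    valid = np.isfinite(b)
    jn, m = b.shape
    p = 1 + m
    eye = np.eye(p)
    fd_eps = 1e-5
    for _ in range(settings.newton_steps):
        q0, ga, gb = _q_and_grad(a, b, r, nodes)
        g = np.concatenate([ga[:, None], gb], axis=1)  # (J, P)
        # forward-difference Hessian of the gradient (batched over items)
        h = np.empty((jn, p, p))
        for pp in range(p):
            a2, b2 = a.copy(), b.copy()
            if pp == 0:
                a2 = a2 + fd_eps
            else:
                b2[:, pp - 1] = b2[:, pp - 1] + fd_eps  # inf stays inf
            _, ga2, gb2 = _q_and_grad(a2, b2, r, nodes)
            h[:, :, pp] = (np.concatenate([ga2[:, None], gb2], axis=1) - g) / fd_eps
        h = 0.5 * (h + np.swapaxes(h, 1, 2))
        # neutralize padded coordinates
        pad = np.concatenate([np.zeros((jn, 1), bool), ~valid], axis=1)  # (J, P)
        for pp in range(p):
            sel = pad[:, pp]
            if sel.any():
                h[sel, pp, :] = 0.0
                h[sel, :, pp] = 0.0
                h[sel, pp, pp] = -1.0
                g[sel, pp] = 0.0
        # shift to negative definite so the solve is an ascent direction
        ev = np.linalg.eigvalsh(h)
        shift = np.maximum(ev.max(axis=1), -1e-6) + 1e-6
        h_nd = h - shift[:, None, None] * eye[None, :, :]
        delta = -np.linalg.solve(h_nd, g[:, :, None])[:, :, 0]
        if not np.all(np.isfinite(delta)):
            delta = np.where(np.isfinite(delta), delta, 0.0)
        # per-item step halving
        t = np.ones(jn)
        active = np.ones(jn, bool)
        a_new, b_new = a.copy(), b.copy()
        for _halve in range(15):
            if not active.any():
                break
            a_try = a + t * delta[:, 0]
            b_try = b + t[:, None] * delta[:, 1:]
            feasible = a_try > settings.min_a
            if m > 1:
                gaps = np.diff(np.where(valid, b_try, np.inf), axis=1)
                feasible &= np.all(np.isnan(gaps) | (gaps > 1e-6), axis=1)
            q_try, _, _ = _q_and_grad(
                np.where(feasible, a_try, a), np.where(feasible[:, None], b_try, b), r, nodes
            )
            accept = active & feasible & (q_try >= q0 - 1e-12)
            a_new = np.where(accept, a_try, a_new)
            b_new = np.where(accept[:, None], b_try, b_new)
            active &= ~accept
            t *= 0.5
        a, b = a_new, b_new
    return a, b


def _starting_values(x: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """a = 1; thresholds from logits of pooled cumulative category proportions."""
    n, jn = x.shape
    a = np.ones(jn)
    b = np.full((jn, kmax - 1), np.inf)
    for j in range(jn):
        kj = int(x[:, j].max()) + 1
        for k in range(1, kj):
            p_ge = np.clip(np.mean(x[:, j] >= k), 1e-3, 1 - 1e-3)
            b[j, k - 1] = float(-np.log(p_ge / (1 - p_ge)))
        # enforce strictly increasing
        for k in range(1, kj - 1):
            if b[j, k] <= b[j, k - 1]:
                b[j, k] = b[j, k - 1] + 0.1
    return a, b


def _param_change(a0, b0, a1, b1) -> float:
    valid = np.isfinite(b0) & np.isfinite(b1)
    change = float(np.max(np.abs(a1 - a0)))
    if valid.any():
        change = max(change, float(np.max(np.abs(b1[valid] - b0[valid]))))
    return change


def _response_matrix(ds) -> tuple[np.ndarray, list[str]]:
    """Accept a ResponseDataset or a plain integer matrix."""
    if hasattr(ds, "responses"):
        x = np.asarray(ds.responses, dtype=int)
        names = list(ds.spec.item_names)
    else:
        x = np.asarray(ds, dtype=int)
        names = [f"item_{j + 1}" for j in range(x.shape[1])]
    if x.ndim != 2:
        raise ValueError("response data must be a 2-D persons x items matrix")
    if x.min() < 0:
        raise ValueError("response matrix contains missing/negative codes; filter first")
    return x, names


def marginal_log_likelihood(ds, params, grid: QuadratureGrid) -> float:
    """Quadrature marginal log-likelihood of the data under fixed parameters.

    ``params`` is a dict item -> GRMItemParams or an ordered list matching the
    dataset's columns.
    """
    x, names = _response_matrix(ds)
    plist = [params[n] for n in names] if isinstance(params, dict) else list(params)
    if len(plist) != x.shape[1]:
        raise ValueError("parameter count does not match item count")
    for j, p in enumerate(plist):
        if x[:, j].max() > len(p.b):
            raise ValueError(
                f"item {j} has observed responses above its top category "
                f"(zero probability under the supplied parameters)"
            )
    a, b = _pack_params(plist)
    ll, _ = _estep(x, a, b, grid.nodes, np.log(grid.weights))
    return ll


# ---------------------------------------------------------------------------
# single-group calibration


def _collapse_sparse_categories(x: np.ndarray, kmax: int) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Remap each item's responses onto its observed categories (contiguous)."""
    x = x.copy()
    collapsed: dict[int, list[int]] = {}
    for j in range(x.shape[1]):
        obs = np.unique(x[:, j])
        expected = np.arange(obs.max() + 1)
        if len(obs) != len(expected) or not np.array_equal(obs, expected):
            mapping = {int(o): i for i, o in enumerate(obs)}
            x[:, j] = np.vectorize(mapping.get)(x[:, j])
            collapsed[j] = [int(o) for o in obs]
    return x, collapsed


def fit_grm(ds, grid: QuadratureGrid | None = None, settings: EMSettings | None = None) -> GRMFit:
    """Calibrate a unidimensional GRM by EM marginal maximum likelihood.

    Items with fewer than two observed categories are excluded with a warning.
    Items with an unobserved intermediate category have that category collapsed
    (recorded in ``fit.collapsed``).  The latent trait prior is the grid's
    weight distribution, N(0, 1) by default.
    """
    grid = grid or QuadratureGrid.normal()
    settings = settings or EMSettings()
    x, names = _response_matrix(ds)

    keep, excluded = [], []
    for j in range(x.shape[1]):
        if len(np.unique(x[:, j])) >= 2:
            keep.append(j)
        else:
            excluded.append(names[j])
            warnings.warn(f"item '{names[j]}' has <2 observed categories; excluded from fit")
    if not keep:
        raise ValueError("no item has at least two observed categories")
    x = x[:, keep]
    kept_names = [names[j] for j in keep]

    x, collapsed_idx = _collapse_sparse_categories(x, int(x.max()) + 1)
    kmax = int(x.max()) + 1
    a, b = _starting_values(x, kmax)
    logw = np.log(grid.weights)

    ll_trace: list[float] = []
    converged = False
    change = np.inf
    it = 0
    for it in range(1, settings.max_iter + 1):
        ll, post = _estep(x, a, b, grid.nodes, logw)
        ll_trace.append(ll)
        r = _expected_counts(x, post, kmax)
        a_new, b_new = _mstep_newton(a, b, r, grid.nodes, settings)
        change = _param_change(a, b, a_new, b_new)
        a, b = a_new, b_new
        if change < settings.tol:
            converged = True
            break
    ll_final, post = _estep(x, a, b, grid.nodes, logw)
    ll_trace.append(ll_final)
    if not converged:
        warnings.warn(
            f"EM did not converge in {settings.max_iter} cycles "
            f"(last max parameter change {change:.2e})"
        )

    plist = _unpack_params(a, b)
    params = dict(zip(kept_names, plist))
    se: dict[str, dict[str, float]] = {}
    if settings.compute_se:
        se = _empirical_standard_errors(x, post, a, b, grid.nodes, kept_names)
    return GRMFit(
        item_names=kept_names,
        params=params,
        log_likelihood=ll_final,
        standard_errors=se,
        converged=converged,
        n_iter=it,
        max_change=float(change),
        ll_trace=ll_trace,
        excluded_items=excluded,
        collapsed={kept_names[j]: cats for j, cats in collapsed_idx.items()},
    )


def _empirical_standard_errors(
    x: np.ndarray,
    post: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    nodes: np.ndarray,
    names: list[str],
) -> dict[str, dict[str, float]]:
    """SEs from the cross-product (empirical Fisher) of per-person scores."""
    n, jn = x.shape
    valid = np.isfinite(b)
    n_par = int(jn + valid.sum())
    scores = np.zeros((n, n_par))
    col = 0
    for j in range(jn):
        mj = int(valid[j].sum())
        kj = mj + 1
        bj = b[j, :mj]
        z = a[j] * (nodes[None, :] - bj[:, None])  # (M, Q)
        pstar = expit(z)
        s = pstar * (1 - pstar)
        upper = np.vstack([np.ones(len(nodes)), pstar])
        lower = np.vstack([pstar, np.zeros(len(nodes))])
        pcat = np.clip(upper - lower, _PROB_FLOOR, None)  # (K, Q)
        # dP_c/da = dP*_c/da - dP*_{c+1}/da with dP*_k/da = s_k (theta - b_k)
        d_th = nodes[None, :] - bj[:, None]
        da_star = s * d_th  # (M, Q), cumulative index 1..M
        da_cat = np.vstack([np.zeros(len(nodes)), da_star]) - np.vstack(
            [da_star, np.zeros(len(nodes))]
        )  # (K, Q)
        dlog_a = da_cat / pcat  # (K, Q)
        xc = x[:, j]
        scores[:, col] = np.sum(post * dlog_a[xc, :], axis=1)
        for k in range(mj):
            # dP*_{k+1}/db_k = -a s_k (0-based threshold k); so
            # dP_k/db_k = +a s_k and dP_{k+1}/db_k = -a s_k
            db_full = np.zeros((kj, len(nodes)))
            db_full[k, :] = a[j] * s[k, :]
            db_full[k + 1, :] = -a[j] * s[k, :]
            dlog_b = db_full / pcat
            scores[:, col + 1 + k] = np.sum(post * dlog_b[xc, :], axis=1)
        col += 1 + mj
    info = scores.T @ scores
    se = np.full(n_par, np.nan)
    try:
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        pass
    out: dict[str, dict[str, float]] = {}
    col = 0
    for j, name in enumerate(names):
        mj = int(valid[j].sum())
        entry = {"a": float(se[col])}
        for k in range(mj):
            entry[f"b{k + 1}"] = float(se[col + 1 + k])
        out[name] = entry
        col += 1 + mj
    return out


# ---------------------------------------------------------------------------
# multi-group calibration


def fit_multigroup_grm(
    ds,
    groups,
    anchor_items: list[str],
    free_items: list[str] | None = None,
    grid: QuadratureGrid | None = None,
    settings: EMSettings | None = None,
    constraints: dict[str, str] | None = None,
) -> GRMFit:
    """Two-group GRM with anchor items constrained equal across groups.

    ``groups`` is a binary vector (0 = reference, 1 = focal).  The reference
    latent distribution is fixed at N(0, 1); the focal mean and SD are
    estimated.  ``constraints`` may refine free items: ``"free"`` (default for
    free items, both a and b group-specific) or ``"b_free"`` (thresholds
    group-specific, discrimination shared).
    """
    grid = grid or QuadratureGrid.normal()
    settings = settings or EMSettings(compute_se=False)
    x, names = _response_matrix(ds)
    groups = np.asarray(groups)
    if groups.shape[0] != x.shape[0]:
        raise ValueError("group vector length must match person count")
    glev = np.unique(groups)
    if len(glev) != 2:
        raise ValueError(f"exactly two groups required, got {list(glev)}")
    is_focal = groups == glev[1]
    if not anchor_items:
        raise ValueError("at least one anchor item is required (model not identified)")
    unknown = [i for i in anchor_items if i not in names]
    if unknown:
        raise ValueError(f"unknown anchor items: {unknown}")
    free_items = free_items if free_items is not None else [n for n in names if n not in anchor_items]
    cons = {n: "equal" for n in anchor_items}
    for n in free_items:
        cons[n] = "free"
    if constraints:
        cons.update(constraints)
    missing = [n for n in names if n not in cons]
    if missing:
        raise ValueError(f"items with no constraint assignment: {missing}")

    x0, x1 = x[~is_focal], x[is_focal]
    if x0.shape[0] == 0 or x1.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    kmax = int(x.max()) + 1
    for j in range(x.shape[1]):
        if len(np.unique(x[:, j])) < 2:
            raise ValueError(f"item '{names[j]}' has <2 observed categories in the pooled data")

    a0, b0 = _starting_values(x, kmax)
    a1, b1 = a0.copy(), b0.copy()
    mu, sd = 0.0, 1.0
    logw0 = np.log(grid.weights)
    equal_mask = np.array([cons[n] == "equal" for n in names])
    free_mask = np.array([cons[n] == "free" for n in names])
    bfree_mask = np.array([cons[n] == "b_free" for n in names])
    nodes = grid.nodes

    ll_trace: list[float] = []
    converged = False
    change = np.inf
    it = 0
    for it in range(1, settings.max_iter + 1):
        logw1 = np.log(grid.reweighted(mu, sd).weights)
        ll_a, post0 = _estep(x0, a0, b0, nodes, logw0)
        ll_b, post1 = _estep(x1, a1, b1, nodes, logw1)
        ll_trace.append(ll_a + ll_b)
        r0 = _expected_counts(x0, post0, kmax)
        r1 = _expected_counts(x1, post1, kmax)

        a0n, b0n, a1n, b1n = a0.copy(), b0.copy(), a1.copy(), b1.copy()
        if equal_mask.any():
            idx = np.where(equal_mask)[0]
            au, bu = _mstep_newton(a0[idx], b0[idx], r0[idx] + r1[idx], nodes, settings)
            a0n[idx] = au
            b0n[idx] = bu
            a1n[idx] = au
            b1n[idx] = bu
        if free_mask.any():
            idx = np.where(free_mask)[0]
            au, bu = _mstep_newton(a0[idx], b0[idx], r0[idx], nodes, settings)
            a0n[idx], b0n[idx] = au, bu
            au, bu = _mstep_newton(a1[idx], b1[idx], r1[idx], nodes, settings)
            a1n[idx], b1n[idx] = au, bu
        for j in np.where(bfree_mask)[0]:
            aj, bj_ref, bj_foc = _fit_b_free_item(
                a0[j], b0[j], b1[j], r0[j], r1[j], nodes, settings
            )
            a0n[j] = a1n[j] = aj
            b0n[j] = bj_ref
            b1n[j] = bj_foc

        e_th = post1 @ nodes
        e_th2 = post1 @ nodes**2
        mu_new = float(e_th.mean())
        sd_new = float(np.sqrt(max(e_th2.mean() - mu_new**2, 1e-4)))

        change = max(
            _param_change(a0, b0, a0n, b0n),
            _param_change(a1, b1, a1n, b1n),
            abs(mu_new - mu),
            abs(sd_new - sd),
        )
        a0, b0, a1, b1, mu, sd = a0n, b0n, a1n, b1n, mu_new, sd_new
        if change < settings.tol:
            converged = True
            break

    logw1 = np.log(grid.reweighted(mu, sd).weights)
    ll_final = _estep(x0, a0, b0, nodes, logw0)[0] + _estep(x1, a1, b1, nodes, logw1)[0]
    ll_trace.append(ll_final)
    if not converged:
        warnings.warn(
            f"multi-group EM did not converge in {settings.max_iter} cycles "
            f"(last max parameter change {change:.2e})"
        )

    ref_params = dict(zip(names, _unpack_params(a0, b0)))
    foc_params = dict(zip(names, _unpack_params(a1, b1)))
    # anchors are exactly shared: reuse the reference objects for the focal dict
    for n in names:
        if cons[n] == "equal":
            foc_params[n] = ref_params[n]
    return GRMFit(
        item_names=names,
        params=ref_params,
        log_likelihood=ll_final,
        standard_errors={},
        converged=converged,
        n_iter=it,
        max_change=float(change),
        ll_trace=ll_trace,
        group_params={"reference": ref_params, "focal": foc_params},
        focal_mean=mu,
        focal_sd=sd,
        anchor_items=[n for n in names if cons[n] == "equal"],
    )


def _fit_b_free_item(
    a_start: float,
    b_ref: np.ndarray,
    b_foc: np.ndarray,
    r_ref: np.ndarray,
    r_foc: np.ndarray,
    nodes: np.ndarray,
    settings: EMSettings,
) -> tuple[float, np.ndarray, np.ndarray]:
    """M-step for an item with shared discrimination, group-specific thresholds."""
    from scipy.optimize import minimize

    m = int(np.isfinite(b_ref).sum())

    def unpack(u):
        a = np.exp(u[0])
        br = np.full_like(b_ref, np.inf)
        bf = np.full_like(b_foc, np.inf)
        br[0] = u[1]
        for k in range(1, m):
            br[k] = br[k - 1] + np.exp(u[1 + k])
        bf[0] = u[1 + m]
        for k in range(1, m):
            bf[k] = bf[k - 1] + np.exp(u[1 + m + k])
        return a, br, bf

    def negq(u):
        a, br, bf = unpack(u)
        aa = np.array([a, a])
        bb = np.vstack([br, bf])
        rr = np.stack([r_ref, r_foc])
        qv, _, _ = _q_and_grad(aa, bb, rr, nodes)
        return -float(qv.sum())

    u0 = np.zeros(1 + 2 * m)
    u0[0] = np.log(max(a_start, settings.min_a))
    br0 = b_ref[np.isfinite(b_ref)]
    bf0 = b_foc[np.isfinite(b_foc)]
    u0[1] = br0[0]
    u0[2 : 1 + m] = np.log(np.maximum(np.diff(br0), 1e-3))
    u0[1 + m] = bf0[0]
    u0[2 + m : 1 + 2 * m] = np.log(np.maximum(np.diff(bf0), 1e-3))
    res = minimize(negq, u0, method="L-BFGS-B", options={"maxiter": 50})
    a, br, bf = unpack(res.x if res.fun <= negq(u0) else u0)
    return float(a), br, bf


# ---------------------------------------------------------------------------
# scoring and curves


def eap_scores(ds, fit_or_params, grid: QuadratureGrid | None = None) -> ThetaEstimates:
    """Expected a posteriori trait estimates under the fitted model.

    The prior is the grid weight distribution (N(0, 1) by default).
    """
    grid = grid or QuadratureGrid.normal()
    x, names = _response_matrix(ds)
    if isinstance(fit_or_params, GRMFit):
        params = fit_or_params.params
        cols = [j for j, n in enumerate(names) if n in params]
        x = x[:, cols]
        plist = [params[names[j]] for j in cols]
    elif isinstance(fit_or_params, dict):
        plist = [fit_or_params[n] for n in names]
    else:
        plist = list(fit_or_params)
    a, b = _pack_params(plist)
    _, post = _estep(x, a, b, grid.nodes, np.log(grid.weights))
    eap = post @ grid.nodes
    e2 = post @ grid.nodes**2
    psd = np.sqrt(np.clip(e2 - eap**2, 0, None))
    return ThetaEstimates(eap=eap, psd=psd)


def tabulate_icc(params_by_group: dict[str, dict[str, GRMItemParams]], theta_grid) :
    """Long-format item characteristic curve table for plotting.

    Columns: group, item, theta, category, probability, expected_score.
    """
    import pandas as pd

    if not params_by_group:
        raise ValueError("at least one group of parameters is required")
    theta_grid = np.asarray(theta_grid, dtype=float)
    rows = []
    for group, params in params_by_group.items():
        for item, p in params.items():
            probs = category_probabilities(p, theta_grid)  # (T, K)
            eis = expected_item_score(p, theta_grid)
            for c in range(p.n_categories):
                for t, th in enumerate(theta_grid):
                    rows.append(
                        {
                            "group": group,
                            "item": item,
                            "theta": float(th),
                            "category": c,
                            "probability": float(probs[t, c]),
                            "expected_score": float(eis[t]),
                        }
                    )
    return pd.DataFrame(rows)
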