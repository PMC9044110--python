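"""Synthetic ordinal item-response generator with planted DIF.

Data are drawn from a two-group graded response model: each person's latent
severity theta comes from a normal distribution (reference fixed at N(0, 1)
for identification; the focal group may differ in mean/SD — "impact"), and
each item response is a draw from the GRM category distribution at that
person's theta under that person's group parameters.

Planted differential item functioning follows the two canonical mechanisms:
*uniform* DIF adds a constant shift to all focal thresholds of an item
(systematically harder or easier at every severity level), *nonuniform* DIF
multiplies the focal discrimination (the curves cross).  Items without
planted DIF share identical parameters across groups, so simulation truth is
always available for recovery and calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MISSING, AlgorithmSpec, ResponseDataset, algorithm_spec
from .grm import GRMItemParams, category_probabilities

__all__ = [
    "PlantedDIF",
    "SimulationDesign",
    "make_clinic_design",
    "simulate_thetas",
    "simulate_responses",
    "simulate_dataset",
    "write_fixture",
]

#: reference-vs-focal group sizes per algorithm, modeled on a large outpatient
#: specialty-clinic sample (race: White vs Black/African American; sex: male
#: vs female)
CLINIC_GROUP_SIZES: dict[str, dict[str, tuple[int, int]]] = {
    "race": {
        "1.1": (289, 289),
        "1.2": (426, 286),
        "2.1": (443, 177),
        "2.2": (211, 207),
        "3": (1782, 660),
    },
    "sex": {
        "1.1": (624, 184),
        "1.2": (841, 198),
        "2.1": (639, 189),
        "2.2": (472, 110),
        "3": (2394, 612),
    },
}

GROUP_LABELS = {
    "race": ("White", "Black/African American"),
    "sex": ("male", "female"),
}


@dataclass(frozen=True)
class PlantedDIF:
    """One planted DIF effect: item, mechanism, magnitude.

    ``magnitude`` is the additive focal threshold shift for uniform DIF and
    the multiplicative focal discrimination factor for nonuniform DIF.
    """

    item: str
    kind: str  # "uniform" | "nonuniform"
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "nonuniform"):
            raise ValueError(f"DIF kind must be 'uniform' or 'nonuniform', got {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("DIF magnitude must be finite")
        if self.kind == "nonuniform" and self.magnitude <= 0:
            raise ValueError("nonuniform DIF magnitude is a discrimination ratio; must be > 0")


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one two-group GRM simulation."""

    spec: AlgorithmSpec
    n_reference: int
    n_focal: int
    impact_mean: float = 0.0
    impact_sd: float = 1.0
    ref_params: dict[str, GRMItemParams] = field(default_factory=dict)
    focal_params: dict[str, GRMItemParams] = field(default_factory=dict)
    planted_dif: tuple[PlantedDIF, ...] = ()
    group_variable: str = "race"
    reference_label: str = "White"
    focal_label: str = "Black/African American"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference <= 0 or self.n_focal <= 0:
            raise ValueError("group sizes must be positive")
        if not (np.isfinite(self.impact_mean) and np.isfinite(self.impact_sd)):
            raise ValueError("impact parameters must be finite")
        if self.impact_sd <= 0:
            raise ValueError("focal latent SD must be positive")
        dif_items = {d.item for d in self.planted_dif}
        for item in self.spec.item_names:
            if item not in self.ref_params or item not in self.focal_params:
                raise ValueError(f"item {item!r} lacks true parameters")
            if item not in dif_items:
                if self.ref_params[item] != self.focal_params[item]:
                    raise ValueError(
                        f"item {item!r} is not in planted_dif but differs across groups"
                    )


def _draw_item_params(
    rng: np.random.Generator,
    n_categories: int,
    a_range: tuple[float, float],
    b1_range: tuple[float, float],
    gap_range: tuple[float, float],
) -> GRMItemParams:
    a = float(rng.uniform(*a_range))
    b1 = float(rng.uniform(*b1_range))
    b = [b1]
    for _ in range(n_categories - 2):
        b.append(b[-1] + float(rng.uniform(*gap_range)))
    return GRMItemParams(a=a, b=tuple(b))


def _apply_dif(params: GRMItemParams, dif: PlantedDIF) -> GRMItemParams:
    if dif.kind == "uniform":
        return GRMItemParams(a=params.a, b=tuple(x + dif.magnitude for x in params.b))
    return GRMItemParams(a=params.a * dif.magnitude, b=params.b)


def make_clinic_design(
    comparison: str,
    algorithm_id: str,
    planted_dif: tuple[PlantedDIF, ...] | list[PlantedDIF] = (),
    impact_mean: float = 0.0,
    impact_sd: float = 1.0,
    seed: int = 0,
    n_reference: int | None = None,
    n_focal: int | None = None,
    a_range: tuple[float, float] = (0.5, 3.5),
    b1_range: tuple[float, float] = (-2.0, 1.5),
    gap_range: tuple[float, float] = (0.5, 1.5),
) -> SimulationDesign:
    """Design with clinic-like group sizes and plausible parameter ranges.

    Default group sizes per algorithm mirror the motivating clinical sample
    (e.g. module 3: 1782 White vs 660 Black/African American; 2394 male vs
    612 female).  True parameters are drawn once from uniform ranges under
    the design seed and then frozen, so generating truth is always available.
    """
    if comparison not in CLINIC_GROUP_SIZES:
        raise ValueError(f"comparison must be one of {sorted(CLINIC_GROUP_SIZES)}")
    spec = algorithm_spec(algorithm_id)
    n_ref_default, n_foc_default = CLINIC_GROUP_SIZES[comparison][algorithm_id]
    rng = np.random.default_rng(seed)
    ref_params: dict[str, GRMItemParams] = {}
    for item in spec.item_names:
        ref_params[item] = _draw_item_params(
            rng, spec.n_categories[item], a_range, b1_range, gap_range
        )
    focal_params = dict(ref_params)
    dif_list = tuple(planted_dif)
    for dif in dif_list:
        if dif.item not in ref_params:
            raise ValueError(f"planted DIF names unknown item {dif.item!r}")
        focal_params[dif.item] = _apply_dif(ref_params[dif.item], dif)
    ref_label, foc_label = GROUP_LABELS[comparison]
    return SimulationDesign(
        spec=spec,
        n_reference=n_reference if n_reference is not None else n_ref_default,
        n_focal=n_focal if n_focal is not None else n_foc_default,
        impact_mean=impact_mean,
        impact_sd=impact_sd,
        ref_params=ref_params,
        focal_params=focal_params,
        planted_dif=dif_list,
        group_variable=comparison,
        reference_label=ref_label,
        focal_label=foc_label,
        seed=seed,
    )


def simulate_thetas(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent traits: reference from N(0, 1), focal from the impact law.

    Returns (thetas, group) where group is 0 for reference, 1 for focal.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    th_ref = rng.normal(0.0, 1.0, size=design.n_reference)
    th_foc = rng.normal(design.impact_mean, design.impact_sd, size=design.n_focal)
    thetas = np.concatenate([th_ref, th_foc])
    group = np.concatenate(
        [np.zeros(design.n_reference, dtype=int), np.ones(design.n_focal, dtype=int)]
    )
    return thetas, group


def simulate_responses(
    thetas: np.ndarray,
    group: np.ndarray,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> ResponseDataset:
    """Draw each response from the GRM category law at that person's theta."""
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    thetas = np.asarray(thetas, dtype=float)
    group = np.asarray(group, dtype=int)
    n = len(thetas)
    spec = design.spec
    resp = np.empty((n, len(spec.item_names)), dtype=int)
    u = rng.random((n, len(spec.item_names)))
    for j, item in enumerate(spec.item_names):
        for g, params_map in ((0, design.ref_params), (1, design.focal_params)):
            mask = group == g
            if not mask.any():
                continue
            probs = category_probabilities(params_map[item], thetas[mask])  # (m, K)
            cum = np.cumsum(probs, axis=1)
            resp[mask, j] = (u[mask, j][:, None] > cum[:, :-1]).sum(axis=1)
    labels = np.where(group == 0, design.reference_label, design.focal_label)
    meta = pd.DataFrame(
        {
            "algorithm": spec.algorithm_id,
            "race": labels if design.group_variable == "race" else "White",
            "ethnicity": "",
            "sex": labels if design.group_variable == "sex" else "male",
        }
    )
    return ResponseDataset(
        responses=resp,
        spec=spec,
        person_ids=np.arange(n),
        group_labels=meta,
        ethnicity_flag=np.zeros(n, dtype=bool),
        recoded=True,
    )


def simulate_dataset(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[ResponseDataset, np.ndarray, np.ndarray]:
    """Convenience wrapper: returns (dataset, thetas, group indicator)."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    thetas, group = simulate_thetas(design, rng)
    ds = simulate_responses(thetas, group, design, rng)
    return ds, thetas, group


def simulate_two_factor_dataset(
    design: SimulationDesign,
    factor_corr: float = 0.5,
    rng: np.random.Generator | None = None,
) -> ResponseDataset:
    """Draw responses from a correlated two-factor GRM (SA and RRB traits).

    SA items respond to the first latent trait, RRB items to the second;
    the traits are standard normal with the given correlation.  Group
    structure and reference-group parameters of ``design`` are reused
    (no DIF is planted on this path).
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    n = design.n_reference + design.n_focal
    cov = np.array([[1.0, factor_corr], [factor_corr, 1.0]])
    traits = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    spec = design.spec
    resp = np.empty((n, len(spec.item_names)), dtype=int)
    u = rng.random((n, len(spec.item_names)))
    for j, item in enumerate(spec.item_names):
        th = traits[:, 0] if spec.construct_map[item] == "SA" else traits[:, 1]
        probs = category_probabilities(design.ref_params[item], th)
        cum = np.cumsum(probs, axis=1)
        resp[:, j] = (u[:, j][:, None] > cum[:, :-1]).sum(axis=1)
    group = np.concatenate(
        [np.zeros(design.n_reference, dtype=int), np.ones(design.n_focal, dtype=int)]
    )
    labels = np.where(group == 0, design.reference_label, design.focal_label)
    meta = pd.DataFrame(
        {
            "algorithm": spec.algorithm_id,
            "race": labels if design.group_variable == "race" else "White",
            "ethnicity": "",
            "sex": labels if design.group_variable == "sex" else "male",
        }
    )
    return ResponseDataset(
        responses=resp,
        spec=spec,
        person_ids=np.arange(n),
        group_labels=meta,
        ethnicity_flag=np.zeros(n, dtype=bool),
        recoded=True,
    )


def write_fixture(ds: ResponseDataset, path) -> None:
    """Write the dataset as a wide CSV readable by ``load_responses``.

    Missing responses are written as empty cells; the round trip reproduces
    the response matrix exactly.
    """
    df = ds.to_frame()
    for item in ds.spec.item_names:
        df[item] = df[item].map(lambda v: "" if v == MISSING else str(int(v)))
    df.to_csv(path, index=False)
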