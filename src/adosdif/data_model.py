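"""Ingest, validate, recode and subset ADOS-2 harmonized-algorithm item data.

The unit of analysis is a wide table: one row per child, 14 harmonized item
scores (10 social-affect and 4 restricted/repetitive-behavior items), a
module-algorithm label, and grouping variables (race, sex, ethnicity).  Raw
item scores live in {0, 1, 2, 3} plus the conventional special codes 7
("other abnormality") and 8 ("not applicable").  Before modeling, top scores
of 3 are collapsed to 2 and the special codes are mapped to 0, mirroring
standard algorithm scoring conventions; both maps are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "AlgorithmSpec",
    "RecodeRules",
    "ResponseDataset",
    "algorithm_spec",
    "load_responses",
    "apply_recodes",
    "complete_case_filter",
    "subset_comparison",
    "describe_items",
]

#: sentinel for a missing item response; distinct from every legal score
MISSING = -1

ALGORITHM_IDS = ("1.1", "1.2", "2.1", "2.2", "3")

#: the ten social-affect items of the harmonized two-construct framework
SA_ITEMS = (
    "eye_contact",
    "gaze",
    "facial_expressions",
    "vocalization",
    "shared_enjoyment",
    "social_overtures",
    "response_joint_attention",
    "gestures",
    "social_response",
    "initiation_joint_attention",
)

#: the four restricted/repetitive-behavior items
RRB_ITEMS = (
    "stereotyped_language",
    "sensory_interest",
    "repetitive_interest",
    "hand_mannerisms",
)

METADATA_COLUMNS = ("person_id", "algorithm", "race", "ethnicity", "sex")


@dataclass(frozen=True)
class AlgorithmSpec:
    """Item layout of one harmonized module-algorithm.

    Exactly 10 items map to the SA construct and 4 to RRB.  After recoding
    every item has 3 categories, except *gaze* in algorithm 1.1 which is
    dichotomous.
    """

    algorithm_id: str
    item_names: tuple[str, ...]
    construct_map: dict[str, str]
    n_categories: dict[str, int]

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHM_IDS:
            raise ValueError(f"unknown algorithm id {self.algorithm_id!r}; expected one of {ALGORITHM_IDS}")
        if len(self.item_names) != 14:
            raise ValueError(f"expected 14 items, got {len(self.item_names)}")
        counts = {"SA": 0, "RRB": 0}
        for item in self.item_names:
            construct = self.construct_map.get(item)
            if construct not in counts:
                raise ValueError(f"item {item!r} has no SA/RRB construct assignment")
            counts[construct] += 1
        if counts != {"SA": 10, "RRB": 4}:
            raise ValueError(f"construct counts must be 10 SA + 4 RRB, got {counts}")
        for item in self.item_names:
            if self.n_categories.get(item) not in (2, 3):
                raise ValueError(f"item {item!r} must have 2 or 3 categories after recoding")

    @property
    def sa_items(self) -> tuple[str, ...]:
        return tuple(i for i in self.item_names if self.construct_map[i] == "SA")

    @property
    def rrb_items(self) -> tuple[str, ...]:
        return tuple(i for i in self.item_names if self.construct_map[i] == "RRB")


def algorithm_spec(algorithm_id: str) -> AlgorithmSpec:
    """Default harmonized item layout for one of the five module-algorithms."""
    items = SA_ITEMS + RRB_ITEMS
    construct = {i: "SA" for i in SA_ITEMS} | {i: "RRB" for i in RRB_ITEMS}
    n_cat = {i: 3 for i in items}
    if algorithm_id == "1.1":
        n_cat["gaze"] = 2  # gaze is dichotomous in module 1, no-words
    return AlgorithmSpec(
        algorithm_id=algorithm_id,
        item_names=items,
        construct_map=construct,
        n_categories=n_cat,
    )


@dataclass(frozen=True)
class RecodeRules:
    """Score recoding applied before IRT modeling.

    ``collapse_top`` folds the top category (3 -> 2 by default); the special
    codes 7 and 8 map to 0 by default, following standard algorithm scoring
    conventions.  Recoding is idempotent.
    """

    collapse_top: dict[int, int] = field(default_factory=lambda: {3: 2})
    special_codes: dict[int, int] = field(default_factory=lambda: {7: 0, 8: 0})

    @property
    def full_map(self) -> dict[int, int]:
        return dict(self.collapse_top) | dict(self.special_codes)


@dataclass(frozen=True)
class ResponseDataset:
    """Persons x items ordinal response matrix plus grouping metadata."""

    responses: np.ndarray
    spec: AlgorithmSpec
    person_ids: np.ndarray
    group_labels: pd.DataFrame
    ethnicity_flag: np.ndarray | None = None
    recoded: bool = False

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses, dtype=int)
        if resp.ndim != 2 or resp.shape[1] != len(self.spec.item_names):
            raise ValueError(
                f"responses must be (persons, {len(self.spec.item_names)}), got {resp.shape}"
            )
        if len(self.person_ids) != resp.shape[0] or len(self.group_labels) != resp.shape[0]:
            raise ValueError("person_ids / group_labels length must match responses rows")
        ids, counts = np.unique(self.person_ids, return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][:5]
            raise ValueError(f"duplicate person identifiers within one algorithm: {list(dup)}")
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "person_ids", np.asarray(self.person_ids))
        object.__setattr__(self, "group_labels", self.group_labels.reset_index(drop=True))
        if self.recoded:
            for j, item in enumerate(self.spec.item_names):
                col = resp[:, j]
                top = self.spec.n_categories[item] - 1
                bad = (col != MISSING) & ((col < 0) | (col > top))
                if bad.any():
                    raise ValueError(
                        f"recoded item {item!r} has values outside [0, {top}]"
                    )

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = self.group_labels.copy()
        df.insert(0, "person_id", self.person_ids)
        for j, item in enumerate(self.spec.item_names):
            df[item] = self.responses[:, j]
        return df


_LEGAL_RAW = {0, 1, 2, 3, 7, 8}
_NA_STRINGS = {"", "na", "nan", "none", "null", "."}


def load_responses(path, spec: AlgorithmSpec, delimiter: str | None = None) -> ResponseDataset:
    """Read a wide delimited file of raw (un-recoded) item scores.

    The header must name every item of ``spec`` plus an ``algorithm`` column;
    ``person_id``, ``race``, ``ethnicity`` and ``sex`` columns are picked up
    when present.  Blank and "NA" cells parse to the missing sentinel.
    Non-integer scores are fatal with the offending row index.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing_cols = [c for c in spec.item_names if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input file lacks item columns: {missing_cols}")
    if "algorithm" not in df.columns:
        raise ValueError("input file lacks an 'algorithm' column")

    n = len(df)
    resp = np.full((n, len(spec.item_names)), MISSING, dtype=int)
    for j, item in enumerate(spec.item_names):
        for i, raw in enumerate(df[item].tolist()):
            s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
            if s.lower() in _NA_STRINGS:
                continue
            try:
                value = int(s)
            except ValueError as exc:
                raise ValueError(
                    f"non-integer score {s!r} for item {item!r} at data row {i}"
                ) from exc
            resp[i, j] = value

    if "person_id" in df.columns:
        person_ids = df["person_id"].to_numpy()
    else:
        person_ids = np.arange(n)
    group_cols = [c for c in ("algorithm", "race", "ethnicity", "sex") if c in df.columns]
    groups = df[group_cols].copy()
    for c in group_cols:
        groups[c] = groups[c].map(lambda v: v.strip() if isinstance(v, str) else v)
    eth = None
    if "ethnicity" in df.columns:
        eth = (
            df["ethnicity"]
            .map(lambda v: str(v).strip().lower() if isinstance(v, str) else "")
            .eq("hispanic")
            .to_numpy()
        )
    ds = ResponseDataset(
        responses=resp,
        spec=spec,
        person_ids=person_ids,
        group_labels=groups,
        ethnicity_flag=eth,
    )
    logger.info("loaded %d persons x %d items from %s", ds.n_persons, ds.n_items, path)
    return ds


def apply_recodes(ds: ResponseDataset, rules: RecodeRules | None = None) -> ResponseDataset:
    """Collapse top scores and map special codes; idempotent.

    Raw scores must lie in {0, 1, 2, 3, 7, 8} (or already be recoded); any
    other code is fatal.
    """
    rules = rules or RecodeRules()
    resp = ds.responses.copy()
    observed = set(np.unique(resp[resp != MISSING]).tolist())
    legal = _LEGAL_RAW | set(rules.full_map.values())
    unknown = observed - legal
    if unknown:
        raise ValueError(f"scores outside the known code set: {sorted(unknown)}")
    changed = 0
    for src, dst in rules.full_map.items():
        mask = resp == src
        changed += int(mask.sum())
        resp[mask] = dst
    logger.info("recoded %d cells (%s)", changed, rules.full_map)
    return replace(ds, responses=resp, recoded=True)


def complete_case_filter(ds: ResponseDataset) -> ResponseDataset:
    """Keep only rows with no missing item response and no missing group label."""
    keep = ~np.any(ds.responses == MISSING, axis=1)
    for c in ds.group_labels.columns:
        if c == "ethnicity":  # optional flag; "not reported" is a legal state
            continue
        col = ds.group_labels[c]
        keep &= col.notna().to_numpy() & (col.astype(str).str.strip() != "").to_numpy()
    dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("complete-case filtering removed every row")
    logger.info("complete-case filter: retained %d, dropped %d", int(keep.sum()), dropped)
    eth = ds.ethnicity_flag[keep] if ds.ethnicity_flag is not None else None
    return replace(
        ds,
        responses=ds.responses[keep],
        person_ids=ds.person_ids[keep],
        group_labels=ds.group_labels.loc[keep].reset_index(drop=True),
        ethnicity_flag=eth,
    )


def subset_comparison(
    ds: ResponseDataset,
    variable: str,
    reference: str,
    focal: str,
    exclude_ethnicity: bool = False,
    min_group_size: int = 50,
) -> ResponseDataset:
    """Restrict to the two compared labels of one grouping variable.

    Labels are matched case-insensitively after trimming.  For the racial
    comparison, Hispanic-flagged rows are dropped first when
    ``exclude_ethnicity`` is set; the flag is ignored for other variables.
    """
    if variable not in ds.group_labels.columns:
        raise ValueError(f"unknown grouping variable {variable!r}")
    keep = np.ones(ds.n_persons, dtype=bool)
    if exclude_ethnicity and variable == "race" and ds.ethnicity_flag is not None:
        keep &= ~ds.ethnicity_flag
        logger.info("ethnicity exclusion dropped %d rows", int(ds.ethnicity_flag.sum()))
    labels = ds.group_labels[variable].astype(str).str.strip().str.lower().to_numpy()
    ref_l, foc_l = reference.strip().lower(), focal.strip().lower()
    is_ref = keep & (labels == ref_l)
    is_foc = keep & (labels == foc_l)
    n_ref, n_foc = int(is_ref.sum()), int(is_foc.sum())
    if min(n_ref, n_foc) < min_group_size:
        raise ValueError(
            f"group sizes too small for comparison on {variable!r}: "
            f"{reference}={n_ref}, {focal}={n_foc} (minimum {min_group_size})"
        )
    sel = is_ref | is_foc
    eth = ds.ethnicity_flag[sel] if ds.ethnicity_flag is not None else None
    logger.info("subset %s: %s=%d vs %s=%d", variable, reference, n_ref, focal, n_foc)
    return replace(
        ds,
        responses=ds.responses[sel],
        person_ids=ds.person_ids[sel],
        group_labels=ds.group_labels.loc[sel].reset_index(drop=True),
        ethnicity_flag=eth,
    )


def group_indicator(ds: ResponseDataset, variable: str, focal: str) -> np.ndarray:
    """Binary focal-group indicator (0 reference, 1 focal), case-insensitive."""
    labels = ds.group_labels[variable].astype(str).str.strip().str.lower().to_numpy()
    return (labels == focal.strip().lower()).astype(int)


def describe_items(ds: ResponseDataset, by: str) -> pd.DataFrame:
    """Per item x group descriptive table: mean, SD (ddof=1), N."""
    if by not in ds.group_labels.columns:
        raise ValueError(f"unknown grouping variable {by!r}")
    labels = ds.group_labels[by].astype(str).str.strip()
    rows = []
    for group in sorted(labels.unique()):
        mask = (labels == group).to_numpy()
        if not mask.any():
            raise ValueError(f"empty group {group!r}")
        sub = ds.responses[mask]
        for j, item in enumerate(ds.spec.item_names):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                raise ValueError(f"group {group!r} has no observations for item {item!r}")
            rows.append(
                {
                    "item": item,
                    "construct": ds.spec.construct_map[item],
                    "group": group,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)) if col.size > 1 else 0.0,
                    "n": int(col.size),
                }
            )
    return pd.DataFrame(rows)
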