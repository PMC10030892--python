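"""Plate preprocessing: control filtering, summary endpoints, series building.

Three steps turn per-well binary incidence records into dose-response
series ready for QC gating and curve fitting:

1. ``filter_control_plates`` drops plates whose vehicle-control wells show
   too much background response (strictly more than the threshold fraction,
   default 50%), evaluated per endpoint.
2. ``derive_summary_endpoints`` adds per-well OR-aggregated endpoints
   (ANY24, TOT_MORT, ANY_MORT, ANY120).
3. ``build_series`` pools wells across the surviving plates into one dose
   group per distinct concentration, with fractional response
   f = affected / living for morphology endpoints.

Denominator convention: endpoints whose definition includes death (MO24,
MORT, TOT_MORT, ANY24, ANY120) use all assayed wells as n — a well that
died has responded, so restricting to living embryos would be circular.
Morphology-only endpoints (everything else, including ANY_MORT) count only
wells with a living embryo at the endpoint's timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import COLUMNS, MORTALITY_CODES

logger = logging.getLogger(__name__)

__all__ = [
    "DoseGroup",
    "DoseResponseSeries",
    "EmptySeriesError",
    "filter_control_plates",
    "derive_summary_endpoints",
    "build_series",
    "iter_series_keys",
    "SUMMARY_ENDPOINTS",
    "ANY24_COMPONENTS",
    "uses_all_wells_denominator",
]

# endpoints derived by OR-aggregation; never raw inputs
SUMMARY_ENDPOINTS = ("ANY24", "TOT_MORT", "ANY_MORT", "ANY120")

ANY24_COMPONENTS = ("MO24", "DP24", "SM24", "NC24")

# n = all assayed wells (the endpoint counts death as a response)
_ALL_WELLS_ENDPOINTS = frozenset(MORTALITY_CODES | {"ANY24", "ANY120"})

_SIG_DIGITS = 6  # canonical rounding for dose-group equality


def uses_all_wells_denominator(endpoint: str) -> bool:
    return endpoint in _ALL_WELLS_ENDPOINTS


def canonical_dose(d) -> np.ndarray:
    """Round concentrations to 6 significant digits for grouping equality."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    nz = d != 0
    if np.any(nz):
        mag = np.floor(np.log10(np.abs(d[nz])))
        factor = 10.0 ** (_SIG_DIGITS - 1 - mag)
        out[nz] = np.round(d[nz] * factor) / factor
    return out


@dataclass(frozen=True)
class DoseGroup:
    """One pooled concentration group: d, wells n, responders y."""

    d: float
    n: int
    y: int

    def __post_init__(self):
        if not (0 <= self.y <= self.n):
            raise ValueError(f"need 0 <= y <= n, got y={self.y}, n={self.n}")
        if self.d < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def f(self) -> float:
        return self.y / self.n if self.n > 0 else float("nan")


@dataclass(frozen=True)
class DoseResponseSeries:
    """A (substance, endpoint) pair with its ordered dose groups."""

    substance_id: str
    endpoint: str
    groups: tuple[DoseGroup, ...]
    substance_kind: str = "chemical"

    def __post_init__(self):
        d = [g.d for g in self.groups]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("dose groups must have strictly increasing concentrations")

    @property
    def d(self) -> np.ndarray:
        return np.array([g.d for g in self.groups], dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.array([g.n for g in self.groups], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([g.y for g in self.groups], dtype=float)

    @property
    def f(self) -> np.ndarray:
        return self.y / self.n

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def d_max(self) -> float:
        return float(self.d.max()) if self.groups else 0.0


class EmptySeriesError(ValueError):
    """No usable wells at any concentration for a (substance, endpoint) pair."""


def filter_control_plates(
    records: pd.DataFrame,
    threshold: float = 0.5,
    endpoint: str | None = None,
) -> tuple[pd.DataFrame, set]:
    """Drop plates whose vehicle controls respond too often.

    A plate is removed iff responding control embryos / total control
    embryos on that plate is *strictly greater* than ``threshold``,
    evaluated on the rows of ``endpoint`` (or on all supplied rows when
    ``endpoint`` is None).  Plates with no control wells are retained with
    a warning.

    Returns (kept rows, set of removed plate_ids).
    """
    df = records
    if endpoint is not None:
        df = df[df["endpoint"] == endpoint]
    if df.empty:
        return df.copy(), set()

    removed = set()
    for plate_id, plate in df.groupby("plate_id"):
        controls = plate[plate["concentration"] == 0]
        if len(controls) == 0:
            logger.warning("plate %s has no vehicle-control wells; retained", plate_id)
            continue
        frac = controls["incidence"].sum() / len(controls)
        if frac > threshold:
            removed.add(plate_id)
            logger.info(
                "plate %s removed: control response %.3f > %.3f", plate_id, frac, threshold
            )
    kept = df[~df["plate_id"].isin(removed)].copy()
    return kept, removed


def _or_aggregate(wide: pd.DataFrame, components: list[str], label: str) -> pd.Series:
    present = [c for c in components if c in wide.columns]
    missing = sorted(set(components) - set(present))
    if missing:
        logger.warning(
            "summary endpoint %s: component endpoint(s) %s absent, treated as 0",
            label, missing,
        )
    if not present:
        return pd.Series(0, index=wide.index, dtype=int)
    return (wide[present].fillna(0).astype(int).max(axis=1)).astype(int)


def derive_summary_endpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Append per-well OR-aggregated summary-endpoint rows.

    ANY24     = OR(MO24, DP24, SM24, NC24), reported at 24 hpf.
    TOT_MORT  = OR(MO24, MORT).
    ANY_MORT  = OR of 120 hpf morphology endpoints (mortality codes excluded);
                the row carries alive = 1 - OR(MO24, MORT) so dead wells drop
                out of the living-embryo denominator.
    ANY120    = OR of every raw 24 h and 120 h endpoint including mortality.

    Existing summary-endpoint rows are recomputed, making the operation
    idempotent; raw rows pass through untouched.
    """
    raw = records[~records["endpoint"].isin(SUMMARY_ENDPOINTS)].copy()
    well_keys = ["plate_id", "well_id", "substance_id", "substance_kind", "concentration"]

    wide = raw.pivot_table(
        index=well_keys, columns="endpoint", values="incidence", aggfunc="max"
    )
    morph120 = sorted(
        set(raw.loc[raw["timepoint"] == 120, "endpoint"]) - MORTALITY_CODES
    )
    all_raw = sorted(set(raw["endpoint"]))

    derived = {
        "ANY24": (_or_aggregate(wide, list(ANY24_COMPONENTS), "ANY24"), 24),
        "TOT_MORT": (_or_aggregate(wide, ["MO24", "MORT"], "TOT_MORT"), 120),
        "ANY_MORT": (_or_aggregate(wide, morph120, "ANY_MORT"), 120),
        "ANY120": (_or_aggregate(wide, all_raw, "ANY120"), 120),
    }
    dead = _or_aggregate(wide, ["MO24", "MORT"], "mortality").astype(bool)

    new_rows = []
    index = wide.index.to_frame(index=False)
    for label, (incidence, timepoint) in derived.items():
        block = index.copy()
        block["endpoint"] = label
        block["incidence"] = incidence.to_numpy()
        if label == "ANY_MORT":
            block["alive"] = (~dead).astype(int).to_numpy()
            # a dead well cannot show (or hide) morphology
            block.loc[block["alive"] == 0, "incidence"] = 0
        else:
            block["alive"] = 1
        block["timepoint"] = timepoint
        new_rows.append(block)

    out = pd.concat([raw] + new_rows, ignore_index=True)
    return out[list(COLUMNS)].reset_index(drop=True)


def build_series(
    records: pd.DataFrame,
    substance_id: str,
    endpoint: str,
) -> DoseResponseSeries:
    """Pool wells into one dose group per distinct concentration.

    For morphology endpoints n counts wells with ``alive == 1`` and y the
    responders among them; for mortality-inclusive endpoints n counts all
    assayed wells.  Groups are sorted by ascending concentration
    (canonically rounded to 6 significant digits); groups left with n = 0
    are dropped with a warning.
    """
    df = records[
        (records["substance_id"] == substance_id) & (records["endpoint"] == endpoint)
    ]
    if df.empty:
        raise EmptySeriesError(f"no wells for ({substance_id!r}, {endpoint!r})")

    kinds = df["substance_kind"].unique()
    if len(kinds) > 1:
        raise ValueError(f"substance {substance_id!r} has mixed kinds {list(kinds)}")

    all_wells = uses_all_wells_denominator(endpoint)
    d = canonical_dose(df["concentration"].to_numpy())
    inc = df["incidence"].to_numpy()
    alive = df["alive"].to_numpy()

    groups = []
    for dose in np.unique(d):
        mask = d == dose
        if all_wells:
            n = int(mask.sum())
            y = int(inc[mask].sum())
        else:
            living = mask & (alive == 1)
            n = int(living.sum())
            y = int(inc[living].sum())
        if n == 0:
            logger.warning(
                "series (%s, %s): dose group d=%g has no living embryos; dropped",
                substance_id, endpoint, dose,
            )
            continue
        groups.append(DoseGroup(d=float(dose), n=n, y=y))

    if not groups:
        raise EmptySeriesError(
            f"series ({substance_id!r}, {endpoint!r}) has no usable dose groups"
        )
    return DoseResponseSeries(
        substance_id=substance_id,
        endpoint=endpoint,
        groups=tuple(groups),
        substance_kind=str(kinds[0]),
    )


def iter_series_keys(records: pd.DataFrame):
    """Yield the distinct (substance_id, endpoint) pairs, sorted."""
    keys = records[["substance_id", "endpoint"]].drop_duplicates()
    yield from sorted(map(tuple, keys.to_numpy()))
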