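"""Plate-level table input, pipeline configuration, and compendium-style CSV output.

Input is a single long-format CSV with one row per (plate, well, substance,
concentration, endpoint) carrying a binary incidence and a viability flag.
A column-name mapping ("dialect") absorbs naming variation in the source
file.  Output is six CSVs mirroring the compendium layout: per substance
kind (chemical vs environmental-sample extract) a dose-response-values
table, a summary-statistics table, and a fitted-curve XY-coordinates table.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "WellRecord",
    "PipelineConfig",
    "read_plate_table",
    "write_outputs",
    "records_to_frame",
    "frame_to_records",
    "COLUMNS",
    "MORTALITY_CODES",
    "OUTPUT_FILES",
]

# canonical long-format schema
COLUMNS = (
    "plate_id",
    "well_id",
    "substance_id",
    "substance_kind",
    "concentration",
    "endpoint",
    "incidence",
    "alive",
    "timepoint",
)

REQUIRED_COLUMNS = ("plate_id", "substance_id", "concentration", "endpoint", "incidence")

MORTALITY_CODES = frozenset({"MO24", "MORT", "TOT_MORT"})

SUBSTANCE_KINDS = ("chemical", "extract")

# released-compendium file names, per substance kind
OUTPUT_FILES: Mapping[str, Mapping[str, str]] = {
    "chemical": {
        "dose_response": "chemdoseResponseVals.csv",
        "summary": "chemSummaryStats.csv",
        "xy": "chemXYcoords.csv",
    },
    "extract": {
        "dose_response": "envSampleResponseVals.csv",
        "summary": "envSampleSummarystats.csv",
        "xy": "envSampleXYcoords.csv",
    },
}

DOSE_RESPONSE_COLUMNS = (
    "substance_id", "endpoint", "concentration", "n_wells", "n_affected", "fraction_affected",
)
SUMMARY_COLUMNS = (
    "substance_id", "endpoint", "qc_score", "qc_reason", "spearman_rho", "flat_p",
    "model", "aic", "chi2", "chi2_p", "bmd10", "bmdl10", "bmd50", "auc",
)
XY_COLUMNS = ("substance_id", "endpoint", "x", "y")


@dataclass(frozen=True)
class WellRecord:
    """One embryo-well observation for one endpoint.

    A vehicle-control well is encoded as ``concentration == 0``.  ``alive``
    is the viability of the embryo at the endpoint's timepoint (for 120 hpf
    morphology endpoints, wells dead at or before 120 hpf carry alive = 0
    and are excluded from the living-embryo denominator downstream).
    """

    plate_id: str
    well_id: str
    substance_id: str
    substance_kind: str
    concentration: float
    endpoint: str
    incidence: int
    alive: int
    timepoint: int

    def __post_init__(self):
        if self.incidence not in (0, 1):
            raise ValueError(f"incidence must be 0/1, got {self.incidence}")
        if self.alive not in (0, 1):
            raise ValueError(f"alive must be 0/1, got {self.alive}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.substance_kind not in SUBSTANCE_KINDS:
            raise ValueError(f"substance_kind must be one of {SUBSTANCE_KINDS}")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the dose-response pipeline.

    control_fail_fraction : plates whose vehicle-control response fraction
        exceeds this are dropped (strictly greater than).
    min_dose_groups : minimum distinct concentration groups (the d = 0
        control counts as a group) required to attempt a fit.
    spearman_min : Spearman rho between dose and fractional response must
        be at least this for a curve to be fitted.
    flat_p_cutoff : flatness-test p-value at or below this earns a Good
        QC score; above it the fit is scored Moderate.
    bmr_levels : benchmark response levels (extra risk) to report.
    bmdl_confidence : one-sided confidence level of the BMD lower bound.
    curve_points : number of XY points sampled along each fitted curve.
    restrict_power : constrain Weibull/gamma power parameters to >= 1.
    seed : base seed for the optimizer's jittered restarts.
    """

    control_fail_fraction: float = 0.5
    min_dose_groups: int = 3
    spearman_min: float = 0.2
    flat_p_cutoff: float = 0.32
    bmr_levels: tuple[float, ...] = (0.10, 0.50)
    bmdl_confidence: float = 0.95
    curve_points: int = 100
    restrict_power: bool = False
    seed: int = 0
    dialect: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("control_fail_fraction", "spearman_min", "flat_p_cutoff", "bmdl_confidence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_dose_groups < 2:
            raise ValueError("min_dose_groups must be >= 2")
        self.bmr_levels = tuple(sorted(float(b) for b in self.bmr_levels))
        if any(not (0.0 < b < 1.0) for b in self.bmr_levels):
            raise ValueError("bmr_levels must lie in (0, 1)")
        if self.curve_points < 2:
            raise ValueError("curve_points must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["bmr_levels"] = list(self.bmr_levels)
        return out


class RowValidationError(ValueError):
    """Raised when input rows violate the well-record invariants."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


def _infer_timepoint(endpoint: pd.Series) -> pd.Series:
    """24 for endpoint codes ending in '24', otherwise 120."""
    return endpoint.astype(str).str.endswith("24").map({True: 24, False: 120})


def read_plate_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format plate CSV into the canonical well-record frame.

    Parameters
    ----------
    path : file path of a CSV with one row per (well, endpoint).
    dialect : optional mapping from canonical column names (see ``COLUMNS``)
        to the column names used in the file.

    Returns
    -------
    DataFrame with the canonical columns, one validated well record per row.

    Raises
    ------
    KeyError if a required column cannot be resolved; RowValidationError
    listing the offending row indices if any row violates an invariant.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    rename = {src: canon for canon, src in dialect.items() if src in df.columns}
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(
            f"required column(s) {missing} not found in {path}; "
            f"available: {list(df.columns)}; dialect={dialect}"
        )

    df = df.copy()
    if "well_id" not in df.columns:
        df["well_id"] = [f"w{i}" for i in range(len(df))]
    if "substance_kind" not in df.columns:
        df["substance_kind"] = "chemical"
    if "timepoint" not in df.columns:
        df["timepoint"] = _infer_timepoint(df["endpoint"])

    bad_kind = ~df["substance_kind"].isin(SUBSTANCE_KINDS)
    if bad_kind.any():
        raise RowValidationError(
            f"substance_kind must be one of {SUBSTANCE_KINDS}; "
            f"offending rows: {list(df.index[bad_kind])}",
            df.index[bad_kind],
        )

    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    df["incidence"] = pd.to_numeric(df["incidence"], errors="coerce")

    bad_conc = df["concentration"].isna() | (df["concentration"] < 0)
    if bad_conc.any():
        raise RowValidationError(
            f"non-numeric or negative concentrations at rows {list(df.index[bad_conc])}",
            df.index[bad_conc],
        )
    bad_inc = ~df["incidence"].isin([0, 1])
    if bad_inc.any():
        raise RowValidationError(
            f"incidence must be 0 or 1; offending rows: {list(df.index[bad_inc])}",
            df.index[bad_inc],
        )

    if "alive" in df.columns:
        df["alive"] = pd.to_numeric(df["alive"], errors="coerce")
        bad_alive = ~df["alive"].isin([0, 1])
        if bad_alive.any():
            raise RowValidationError(
                f"alive must be 0 or 1; offending rows: {list(df.index[bad_alive])}",
                df.index[bad_alive],
            )
    else:
        # viability not recorded: assume alive except a positive mortality call
        dead = df["endpoint"].isin(MORTALITY_CODES) & (df["incidence"] == 1)
        df["alive"] = np.where(dead, 0, 1)
        logger.warning(
            "input has no 'alive' column; defaulting alive=1 except mortality "
            "endpoints with incidence 1"
        )

    df = df[list(COLUMNS)].astype(
        {
            "plate_id": str, "well_id": str, "substance_id": str,
            "substance_kind": str, "concentration": float, "endpoint": str,
            "incidence": int, "alive": int, "timepoint": int,
        }
    )
    return df.reset_index(drop=True)


def records_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=list(COLUMNS))
    return pd.DataFrame(rows)[list(COLUMNS)]


def frame_to_records(df: pd.DataFrame) -> list[WellRecord]:
    return [WellRecord(**row) for row in df[list(COLUMNS)].to_dict("records")]


def write_plate_table(df: pd.DataFrame, path) -> None:
    """Write a canonical well-record frame as the long-format CSV."""
    df[list(COLUMNS)].to_csv(path, index=False)


def _fmt(x):
    if x is None:
        return ""
    if isinstance(x, float) and not np.isfinite(x):
        return ""
    return x


def write_outputs(results, out_dir) -> list[str]:
    """Write the six compendium-style CSVs for a collection of series results.

    ``results`` is an iterable of objects with attributes ``series`` (with
    ``substance_id``, ``endpoint``, ``substance_kind`` and dose groups),
    ``qc`` (score/reason/spearman_rho/flat_p), and — for fitted series —
    ``best`` (the selected ModelFit), ``bmd`` (mapping BMR -> BMDEstimate),
    ``auc`` and ``curve`` (the XY array).  Series scored Poor contribute a
    summary row with empty fit fields and no XY rows.

    Returns the list of file paths written (all six, header-only when a
    substance kind has no series).
    """
    os.makedirs(out_dir, exist_ok=True)
    tables = {
        kind: {"dose_response": [], "summary": [], "xy": []}
        for kind in SUBSTANCE_KINDS
    }

    for res in results:
        series = res.series
        kind = series.substance_kind
        key = (series.substance_id, series.endpoint)
        for grp in series.groups:
            tables[kind]["dose_response"].append(
                (*key, grp.d, grp.n, grp.y, grp.f)
            )
        qc = res.qc
        best = getattr(res, "best", None)
        bmd = getattr(res, "bmd", None) or {}
        row = {
            "substance_id": key[0],
            "endpoint": key[1],
            "qc_score": qc.score,
            "qc_reason": qc.reason,
            "spearman_rho": _fmt(qc.spearman_rho),
            "flat_p": _fmt(qc.flat_p),
            "model": best.model if best is not None else "",
            "aic": _fmt(best.aic) if best is not None else "",
            "chi2": _fmt(best.chi2) if best is not None else "",
            "chi2_p": _fmt(best.p_fit) if best is not None else "",
            "bmd10": _fmt(bmd[0.10].bmd) if 0.10 in bmd else "",
            "bmdl10": _fmt(bmd[0.10].bmdl) if 0.10 in bmd else "",
            "bmd50": _fmt(bmd[0.50].bmd) if 0.50 in bmd else "",
            "auc": _fmt(getattr(res, "auc", None)),
        }
        tables[kind]["summary"].append(tuple(row[c] for c in SUMMARY_COLUMNS))
        curve = getattr(res, "curve", None)
        if best is not None and curve is not None:
            for x, y in curve:
                tables[kind]["xy"].append((*key, x, y))

    schema = {
        "dose_response": DOSE_RESPONSE_COLUMNS,
        "summary": SUMMARY_COLUMNS,
        "xy": XY_COLUMNS,
    }
    paths = []
    for kind in SUBSTANCE_KINDS:
        for table, columns in schema.items():
            path = os.path.join(out_dir, OUTPUT_FILES[kind][table])
            pd.DataFrame(tables[kind][table], columns=list(columns)).to_csv(
                path, index=False
            )
            paths.append(path)
    return paths
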