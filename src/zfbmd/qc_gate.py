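"""Quality-control gate ahead of curve fitting.

A (substance, endpoint) series may only be fitted when it has at least
``min_dose_groups`` distinct concentration groups (the vehicle control
counts as one) and a non-trivial increasing dose-response trend, measured
as the Spearman rank correlation between concentration and fractional
response at or above ``spearman_min``.  Series failing either check are
scored Poor and bypass fitting entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import DoseResponseSeries

__all__ = ["QCRecord", "check_min_groups", "check_trend", "gate", "POOR_REASONS"]

POOR_REASONS = ("too_few_groups", "no_trend", "fit_failed")


@dataclass
class QCRecord:
    """Per-series QC badge plus the gate statistics that produced it.

    ``score`` is one of Poor/Moderate/Good once the pipeline finishes;
    the gate emits either a Poor record or a proceed record (score None)
    carrying the Spearman rho, which fitting later upgrades.
    """

    score: str | None
    reason: str
    spearman_rho: float | None = None
    flat_p: float | None = None

    def __post_init__(self):
        if self.score == "Poor" and self.reason not in POOR_REASONS:
            raise ValueError(f"Poor requires a failure reason, got {self.reason!r}")
        if self.score in ("Moderate", "Good") and self.reason != "ok":
            raise ValueError("non-Poor scores must carry reason 'ok'")

    @property
    def proceed(self) -> bool:
        return self.score is None


def check_min_groups(series: DoseResponseSeries, k: int = 3) -> bool:
    """True iff the series has at least ``k`` distinct concentration groups."""
    return series.n_groups >= k


def check_trend(
    series: DoseResponseSeries, rho_min: float = 0.2
) -> tuple[float, bool]:
    """Spearman rank correlation between dose and fractional response.

    One (d, f) pair per group, average ranks for ties.  Returns
    (rho, rho >= rho_min).  A series with identical f everywhere has an
    undefined rho (returned as nan) and fails: a flat curve is a no-fit case.

    rho is canonically rounded to 12 decimals so the at-threshold boundary
    (a passing rho exactly equal to rho_min) is immune to float noise.
    """
    d, f = series.d, series.f
    if np.all(f == f[0]):
        return float("nan"), False
    rho = stats.spearmanr(d, f).statistic
    if not np.isfinite(rho):
        return float("nan"), False
    rho = round(float(rho), 12)
    return rho, bool(rho >= rho_min)


def gate(series: DoseResponseSeries, config) -> QCRecord:
    """Run both checks; Poor records bypass fitting downstream.

    Returns a QCRecord: score "Poor" with the failing reason, or score None
    ("proceed") carrying the Spearman rho for the summary table.
    """
    if not check_min_groups(series, config.min_dose_groups):
        return QCRecord(score="Poor", reason="too_few_groups")
    rho, ok = check_trend(series, config.spearman_min)
    if not ok:
        return QCRecord(score="Poor", reason="no_trend", spearman_rho=rho)
    return QCRecord(score=None, reason="ok", spearman_rho=rho)
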