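"""End-to-end orchestration: records in, per-series results and tallies out.

``process_series`` runs one (substance, endpoint) pair through control-
plate filtering, series building, QC gating, eight-family fitting, AIC
selection and benchmark-dose estimation.  ``run_records`` maps it over
every pair in a record table and ``build_manifest`` summarizes the run in
the Poor/Moderate/Good tally layout used for QC reporting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bmd_estim import BMDEstimate, curve_auc, curve_xy, estimate_bmds
from .fitting import ModelFit, fit_all_models, select_model
from .plate_io import PipelineConfig
from .preprocess import (
    DoseResponseSeries,
    EmptySeriesError,
    build_series,
    derive_summary_endpoints,
    filter_control_plates,
    iter_series_keys,
)
from .qc_gate import QCRecord, gate

logger = logging.getLogger(__name__)

__all__ = ["SeriesResult", "process_series", "run_records", "build_manifest"]


@dataclass
class SeriesResult:
    """Everything the output tables need for one (substance, endpoint) pair."""

    series: DoseResponseSeries
    qc: QCRecord
    fits: list[ModelFit] | None = None
    best: ModelFit | None = None
    bmd: dict[float, BMDEstimate] = field(default_factory=dict)
    auc: float = float("nan")
    curve: np.ndarray | None = None


def process_series(
    records: pd.DataFrame,
    substance_id: str,
    endpoint: str,
    config: PipelineConfig,
    compute_bmdl: bool = True,
    models=None,
) -> SeriesResult:
    """Run the full per-series pipeline; Poor series skip fitting entirely.

    ``models`` restricts the fitted families (default all eight) — used by
    calibration experiments that study one family in isolation.
    """
    kept, removed = filter_control_plates(
        records, config.control_fail_fraction, endpoint
    )
    if removed:
        logger.info(
            "series (%s, %s): removed %d plate(s) on the control check: %s",
            substance_id, endpoint, len(removed), sorted(removed),
        )
    series = build_series(kept, substance_id, endpoint)

    qc = gate(series, config)
    if not qc.proceed:
        logger.info("series (%s, %s): Poor (%s)", substance_id, endpoint, qc.reason)
        return SeriesResult(series=series, qc=qc)

    fits = fit_all_models(series, config, models=models)
    best, qc_fit = select_model(fits, series, config)
    qc_fit.spearman_rho = qc.spearman_rho
    if best is None:
        logger.info("series (%s, %s): Poor (fit_failed)", substance_id, endpoint)
        return SeriesResult(series=series, qc=qc_fit, fits=fits)

    bmds = estimate_bmds(
        best, series,
        bmr_levels=config.bmr_levels,
        confidence=config.bmdl_confidence,
        bmdl_levels=(0.10,) if compute_bmdl else (),
    )
    d_max = series.d_max
    result = SeriesResult(
        series=series,
        qc=qc_fit,
        fits=fits,
        best=best,
        bmd=bmds,
        auc=curve_auc(best, d_max),
        curve=curve_xy(best, d_max, config.curve_points),
    )
    logger.info(
        "series (%s, %s): %s, model=%s AIC=%.3f", substance_id, endpoint,
        qc_fit.score, best.model, best.aic,
    )
    return result


def run_records(
    records: pd.DataFrame,
    config: PipelineConfig,
    derive_summaries: bool = True,
) -> list[SeriesResult]:
    """Process every (substance, endpoint) pair present in the table.

    Summary endpoints (ANY24, TOT_MORT, ANY_MORT, ANY120) are derived first
    unless disabled.  A series that cannot be built (no usable wells) is
    logged and skipped; the run continues.
    """
    if records.empty:
        raise ValueError("input contains no well records")
    if derive_summaries:
        records = derive_summary_endpoints(records)
    results = []
    for substance_id, endpoint in iter_series_keys(records):
        try:
            results.append(process_series(records, substance_id, endpoint, config))
        except EmptySeriesError as exc:
            logger.warning("series (%s, %s) skipped: %s", substance_id, endpoint, exc)
    return results


def build_manifest(
    results: list[SeriesResult],
    config: PipelineConfig,
    input_digest: str | None = None,
) -> dict:
    """Run manifest: config snapshot, input digest, per-kind QC tallies."""
    tallies = {
        kind: {"Poor": 0, "Moderate": 0, "Good": 0}
        for kind in ("chemical", "extract")
    }
    for res in results:
        tallies[res.series.substance_kind][res.qc.score] += 1
    return {
        "tool": "zfbmd",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "input_sha256": input_digest,
        "n_series": len(results),
        "qc_tallies": tallies,
    }


def digest_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
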