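"""Synthetic plate-structured screens with known ground truth.

Emulates the data structure of a high-throughput zebrafish developmental
screen: round-bottom 96-well plates with one embryo per well, vehicle
control wells at concentration 0, ~32 wells per (substance, concentration)
condition split across plates, binary incidence per endpoint, and
independent early (24 hpf) mortality that removes wells from the
living-embryo denominator of later morphology endpoints.

Responses are drawn from a known quantal curve, so the true benchmark dose
is available in closed form and the whole pipeline can be validated by
parameter-recovery and confidence-bound-coverage experiments
(:func:`recovery_experiment`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .plate_io import COLUMNS, MORTALITY_CODES, PipelineConfig
from .models import extra_risk, get_model

__all__ = [
    "SimulationDesign",
    "simulate_plates",
    "simulate_screen",
    "true_bmd",
    "recovery_experiment",
]

# Default dose series: vehicle control plus a ~3.2x dilution ladder up to
# the 50 uM chemical screening maximum.
_DEFAULT_DOSES = (0.0, 0.5, 1.6, 5.0, 16.0, 50.0)


@dataclass(frozen=True)
class SimulationDesign:
    """One simulated (substance, endpoint) screening condition.

    Defaults mirror the screening design the pipeline targets: 32 wells per
    condition spread over 4 plates (8 per plate), 8 vehicle-control wells
    per plate, doses up to 50 uM, a ~12% background response rate, and a
    small 24 hpf mortality rate.  ``theta_true`` defaults to a quantal-
    linear curve with background ``background_rate`` and slope 0.05/uM.
    """

    doses: tuple[float, ...] = _DEFAULT_DOSES
    wells_per_group: int = 32
    plates: int = 4
    control_wells_per_plate: int = 8
    substance_id: str = "CHEM-0001"
    substance_kind: str = "chemical"
    endpoint: str = "EDEM"
    endpoint_timepoint: int = 120
    true_model: str = "quantal_linear"
    theta_true: tuple[float, ...] | None = None
    mortality_rate_24h: float = 0.02
    background_rate: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if 0.0 not in self.doses:
            raise ValueError("doses must include the vehicle control 0")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be distinct")
        if self.wells_per_group < 1:
            raise ValueError("wells_per_group must be >= 1")
        if self.plates < 1 or self.control_wells_per_plate < 1:
            raise ValueError("plates and control_wells_per_plate must be >= 1")
        for name in ("mortality_rate_24h", "background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        get_model(self.true_model)  # raises on unknown family

    @property
    def theta(self) -> np.ndarray:
        if self.theta_true is not None:
            return np.asarray(self.theta_true, dtype=float)
        if self.true_model != "quantal_linear":
            raise ValueError("theta_true is required for non-default true models")
        return np.array([self.background_rate, 0.05])

    def p_true(self, d) -> np.ndarray:
        return get_model(self.true_model).predict(self.theta, d)

    def replace(self, **kw) -> "SimulationDesign":
        return dataclasses.replace(self, **kw)


def true_bmd(design: SimulationDesign, bmr: float = 0.10) -> float:
    """Ground-truth BMD of the generating curve (extra-risk definition)."""
    model, theta = design.true_model, design.theta

    def g(d):
        return float(extra_risk(model, theta, d)) - bmr

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            return float("nan")
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-14, rtol=4 * np.finfo(float).eps))


def simulate_plates(design: SimulationDesign) -> pd.DataFrame:
    """Draw one plate-structured dataset; fully reproducible from the seed.

    Each well first draws 24 hpf death Bernoulli(mortality_rate_24h); dead
    wells get an MO24 incidence of 1 and are excluded (alive = 0) from the
    morphology endpoint.  Surviving wells draw the endpoint incidence
    Bernoulli(p_true(d)).  When the designed endpoint is itself a mortality
    code, its incidence is drawn directly from the true curve instead.
    """
    rng = np.random.default_rng(design.seed)
    mortality_endpoint = design.endpoint in MORTALITY_CODES

    # well layout: controls first on each plate, then round-robin treatment wells
    doses, plates = [], []
    for dose in design.doses:
        if dose == 0.0:
            for plate in range(design.plates):
                doses += [0.0] * design.control_wells_per_plate
                plates += [plate] * design.control_wells_per_plate
        else:
            doses += [dose] * design.wells_per_group
            plates += [i % design.plates for i in range(design.wells_per_group)]
    doses = np.asarray(doses)
    plates = np.asarray(plates)

    well_no = np.zeros(len(doses), dtype=int)
    for plate in range(design.plates):
        mask = plates == plate
        well_no[mask] = np.arange(1, mask.sum() + 1)
    plate_ids = np.array([f"P{p + 1:02d}" for p in plates])
    well_ids = np.array([f"{pid}-W{w:02d}" for pid, w in zip(plate_ids, well_no)])

    p = np.asarray(design.p_true(doses), dtype=float)

    def frame(endpoint, incidence, alive, timepoint):
        return pd.DataFrame({
            "plate_id": plate_ids, "well_id": well_ids,
            "substance_id": design.substance_id,
            "substance_kind": design.substance_kind,
            "concentration": doses, "endpoint": endpoint,
            "incidence": incidence.astype(int), "alive": alive.astype(int),
            "timepoint": timepoint,
        })

    if mortality_endpoint:
        inc = rng.random(len(doses)) < p
        out = frame(design.endpoint, inc, ~inc, design.endpoint_timepoint)
    else:
        # the rng is consumed well-by-well (death first, then morphology) so
        # the draw order is layout-stable
        draws = rng.random((len(doses), 2))
        dead24 = draws[:, 0] < design.mortality_rate_24h
        inc = (draws[:, 1] < p) & ~dead24
        out = pd.concat(
            [
                frame("MO24", dead24, ~dead24, 24),
                frame(design.endpoint, inc, ~dead24, design.endpoint_timepoint),
            ],
            ignore_index=True,
        )
    return out[list(COLUMNS)]


def simulate_screen(designs) -> pd.DataFrame:
    """Concatenate several simulated conditions into one screen table."""
    frames = [simulate_plates(d) for d in designs]
    return pd.concat(frames, ignore_index=True)


def recovery_experiment(
    design: SimulationDesign,
    replicates: int,
    config: PipelineConfig | None = None,
    bmr: float = 0.10,
    compute_bmdl: bool = True,
    models=None,
) -> dict:
    """Run the pipeline on many simulated replicates; summarize recovery.

    Per replicate: simulate, preprocess, gate, fit, select by AIC, and
    estimate the BMD (and BMDL when ``compute_bmdl``).  Reports bias and
    error of the estimated BMD relative to the generating curve's true BMD,
    and the fraction of replicates whose BMDL lies at or below the true BMD
    (the one-sided coverage the bound is designed for).

    ``models`` restricts the fitted families.  Passing the generating
    family alone measures the estimator's own consistency and the profile
    bound's calibration; the default (all eight with AIC selection) adds
    model-selection uncertainty on top — see docs/methods.md.
    """
    from .pipeline import process_series

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or PipelineConfig(seed=design.seed)
    target = true_bmd(design, bmr)

    rng = np.random.default_rng(design.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    rel_errors, bmds, cover_hits, n_bmdl = [], [], 0, 0
    n_gated, n_fit = 0, 0
    for rep_seed in child_seeds:
        records = simulate_plates(design.replace(seed=int(rep_seed)))
        rep_config = dataclasses.replace(config, seed=int(rep_seed))
        result = process_series(
            records, design.substance_id, design.endpoint, rep_config,
            compute_bmdl=compute_bmdl, models=models,
        )
        if result.qc.score == "Poor":
            n_gated += 1
            continue
        est = result.bmd.get(round(bmr, 6))
        if est is None or not np.isfinite(est.bmd):
            continue
        n_fit += 1
        bmds.append(est.bmd)
        rel_errors.append((est.bmd - target) / target)
        if compute_bmdl and np.isfinite(est.bmdl):
            n_bmdl += 1
            if est.bmdl <= target:
                cover_hits += 1

    rel = np.asarray(rel_errors)
    return {
        "replicates": replicates,
        "n_poor": n_gated,
        "n_estimated": n_fit,
        "true_bmd": target,
        "mean_bmd": float(np.mean(bmds)) if bmds else float("nan"),
        "bias": float(np.mean(rel)) if rel.size else float("nan"),
        "median_abs_rel_error": float(np.median(np.abs(rel))) if rel.size else float("nan"),
        "rmse_rel": float(np.sqrt(np.mean(rel**2))) if rel.size else float("nan"),
        "n_bmdl": n_bmdl,
        "coverage": cover_hits / n_bmdl if n_bmdl else float("nan"),
    }
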