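"""Benchmark-dose estimation: BMD, profile-likelihood BMDL, curve XY, AUC.

The benchmark dose at benchmark response (BMR) level ``r`` solves the
extra-risk equation

    (p(bmd) - p(0)) / (1 - p(0)) = r,

found by bracketed root search on the fitted curve.  The BMDL is the lower
limit of a one-sided confidence interval on the BMD, computed by profile
likelihood: each family is reparameterized so the BMD is an explicit
parameter (the slope-type parameter is solved from the extra-risk equation
in closed form), the remaining parameters are re-optimized at each
candidate BMD value, and the bound is the smallest candidate whose
log-likelihood drop from the maximum stays within the chi-square cutoff
``chi2_1(1 - 2 (1 - confidence))`` (2.70554 for a one-sided 95% bound).

All root finding and profiling happens in normalized dose units (doses
divided by the series maximum), so BMD and BMDL are exactly equivariant
under a change of dose units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaincinv, logit, ndtr, ndtri

from .fitting import ModelFit
from .models import P_EPS, get_model
from .preprocess import DoseResponseSeries

logger = logging.getLogger(__name__)

__all__ = [
    "BMDEstimate",
    "compute_bmd",
    "compute_bmdl",
    "curve_xy",
    "curve_auc",
    "PROFILE_CUTOFF_95",
]

# chi2_1 90% quantile: one-sided 95% profile-likelihood cutoff
PROFILE_CUTOFF_95 = float(stats.chi2.ppf(0.9, 1))

_BRACKET_FACTOR = 10.0  # search for the BMD up to 10x the top tested dose


@dataclass(frozen=True)
class BMDEstimate:
    """BMD at one benchmark response level with its one-sided lower bound."""

    bmr: float
    bmd: float
    bmdl: float
    confidence: float = 0.95

    @property
    def defined(self) -> bool:
        return np.isfinite(self.bmd)


def _extra_risk_norm(fit: ModelFit, u) -> np.ndarray:
    spec = fit.spec
    p0 = min(spec.predict(fit.theta, 0.0), 1.0 - 1e-12)
    return (spec.predict(fit.theta, u) - p0) / (1.0 - p0)


def compute_bmd(fit: ModelFit, bmr: float, d_max: float | None = None) -> float:
    """Dose at which the fitted extra risk equals ``bmr`` (input units).

    The root is bracketed on [0, 10 x d_max] (d_max defaults to the fit's
    dose scale, i.e. the top tested dose).  Returns nan when the fitted
    curve never reaches the benchmark response within the bracket (e.g. a
    flat curve).
    """
    if not (0.0 < bmr < 1.0):
        raise ValueError("bmr must lie in (0, 1)")
    hi_natural = _BRACKET_FACTOR * (d_max if d_max is not None else fit.dose_scale)
    hi = hi_natural / fit.dose_scale
    if _extra_risk_norm(fit, hi) < bmr:
        return float("nan")

    def g(u):
        return _extra_risk_norm(fit, u) - bmr

    root = optimize.brentq(g, 0.0, hi, xtol=1e-14, rtol=4 * np.finfo(float).eps)
    return float(root * fit.dose_scale)


# --- profile-likelihood reparameterizations --------------------------------
# For each family: free nuisance parameters, their optimizer bounds, a map
# (free, beta) -> full theta with the BMD pinned at beta (normalized dose
# units), and the projection of a fitted theta onto the free parameters.


def _profile_spec(model: str, bmr: float, restrict_power: bool):
    A = -np.log1p(-bmr)  # -ln(1 - bmr)
    alpha_lo = 1.0 if restrict_power else 1e-3
    g_box = (0.0, 0.999)

    if model == "quantal_linear":
        return (
            [g_box],
            lambda free, beta: (free[0], A / beta),
            lambda th: (th[0],),
        )
    if model == "weibull":
        return (
            [g_box, (alpha_lo, 18.0)],
            lambda free, beta: (free[0], free[1], A / beta ** free[1]),
            lambda th: (th[0], th[1]),
        )
    if model == "gamma":
        return (
            [g_box, (alpha_lo, 18.0)],
            lambda free, beta: (free[0], free[1], gammaincinv(free[1], bmr) / beta),
            lambda th: (th[0], th[1]),
        )
    if model == "multistage2":
        # t in [0, 1] splits the pinned total hazard A between b1 and b2
        def build(free, beta):
            g, t = free
            return (g, A * (1.0 - t) / beta, A * t / beta**2)

        def project(th):
            g, b1, b2 = th
            total = b1 + b2  # crude split ratio for the start value
            t = 0.0 if total == 0 else float(np.clip(b2 / total, 0.0, 1.0))
            return (g, t)

        return ([g_box, (0.0, 1.0)], build, project)
    if model == "log_logistic":
        c = logit(bmr)
        return (
            [g_box, (1e-6, 40.0)],
            lambda free, beta: (free[0], c - free[1] * np.log(beta), free[1]),
            lambda th: (th[0], max(th[2], 1e-6)),
        )
    if model == "log_probit":
        c = ndtri(bmr)
        return (
            [g_box, (1e-6, 20.0)],
            lambda free, beta: (free[0], c - free[1] * np.log(beta), free[1]),
            lambda th: (th[0], max(th[2], 1e-6)),
        )
    if model == "logistic":
        def build(free, beta):
            a = free[0]
            p0 = expit(a)
            pt = p0 + bmr * (1.0 - p0)
            return (a, (logit(pt) - a) / beta)

        return ([(-18.0, 18.0)], build, lambda th: (th[0],))
    if model == "probit":
        def build(free, beta):
            a = free[0]
            p0 = ndtr(a)
            pt = min(p0 + bmr * (1.0 - p0), 1.0 - 1e-14)
            return (a, (ndtri(pt) - a) / beta)

        return ([(-8.0, 8.0)], build, lambda th: (th[0],))
    raise KeyError(f"no profile parameterization for model {model!r}")


def _profile_loglik(predict, build, beta, bounds, starts, u, y, n):
    """Maximize the constrained log-likelihood at BMD = beta."""

    def nll(free):
        theta = build(tuple(free), beta)
        p = np.clip(predict(theta, u), P_EPS, 1.0 - P_EPS)
        return -float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))

    best_ll = -np.inf
    best_free = None
    for x0 in starts:
        x0 = tuple(float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(x0, bounds))
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll = -float(res.fun)
            best_free = tuple(res.x)
    return best_ll, best_free


def compute_bmdl(
    fit: ModelFit,
    series: DoseResponseSeries,
    bmr: float = 0.10,
    confidence: float = 0.95,
) -> float:
    """Profile-likelihood lower confidence bound on the BMD (input units).

    Candidates beta < BMD are scanned geometrically (factor 0.75) until the
    profile deviance 2 (LL_max - LL_profile) exceeds the one-sided cutoff,
    then the crossing is located by Brent root finding to 1e-8 relative
    precision.  Returns nan (with a log message) if the profile likelihood
    never drops below the cutoff down to a negligible dose, or if the BMD
    itself is undefined.
    """
    if not (0.5 < confidence < 1.0):
        raise ValueError("confidence must lie in (0.5, 1)")
    bmd = compute_bmd(fit, bmr)
    if not np.isfinite(bmd):
        return float("nan")
    beta_hat = bmd / fit.dose_scale
    cutoff = float(stats.chi2.ppf(2.0 * confidence - 1.0, 1))

    spec = fit.spec
    u = series.d / fit.dose_scale
    y, n = series.y, series.n
    bounds, build, project = _profile_spec(
        fit.model, bmr, restrict_power=False
    )
    hat_free = project(tuple(fit.theta))
    generic = tuple(0.5 * (lo + min(hi, 10.0)) for lo, hi in bounds)

    ll_max = fit.loglik
    warm = {"free": hat_free}

    def deviance(beta):
        nonlocal ll_max
        starts = [warm["free"], hat_free, generic]
        ll, free = _profile_loglik(
            spec._predict, build, beta, bounds, starts, u, y, n
        )
        if free is not None:
            warm["free"] = free
        if ll > ll_max:  # profiling found a better optimum than the fit
            ll_max = ll
        return 2.0 * (ll_max - ll)

    # geometric walk down from the BMD until the cutoff is crossed
    hi = beta_hat
    d_hi = 0.0
    crossed = False
    for k in range(1, 121):
        lo = beta_hat * 0.75**k
        d_lo = deviance(lo)
        if d_lo >= cutoff:
            crossed = True
            break
        hi, d_hi = lo, d_lo
    if not crossed:
        logger.warning(
            "BMDL undefined for (%s, %s) model %s: profile never reached the "
            "cutoff", series.substance_id, series.endpoint, fit.model,
        )
        return float("nan")

    root = optimize.brentq(
        lambda b: deviance(b) - cutoff, lo, hi, rtol=1e-8, xtol=1e-300
    )
    return float(root * fit.dose_scale)


def curve_xy(fit: ModelFit, d_max: float, points: int = 100) -> np.ndarray:
    """Fitted-curve coordinates on a uniform dose grid including 0 and d_max."""
    if points < 2:
        raise ValueError("points must be >= 2")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    x = np.linspace(0.0, d_max, points)
    y = fit.predict(x)
    return np.column_stack([x, np.atleast_1d(y)])


def curve_auc(fit: ModelFit, d_max: float, n_grid: int = 2049) -> float:
    """Trapezoidal area under the fitted curve over [0, d_max], / d_max.

    Normalization by the dose range keeps the value in [0, 1] and
    comparable across substances with different tested ranges.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    x = np.linspace(0.0, d_max, n_grid)
    y = np.atleast_1d(fit.predict(x))
    return float(np.trapezoid(y, x) / d_max)


def estimate_bmds(
    fit: ModelFit,
    series: DoseResponseSeries,
    bmr_levels=(0.10, 0.50),
    confidence: float = 0.95,
    bmdl_levels=(0.10,),
) -> dict[float, BMDEstimate]:
    """BMD at each requested level; BMDL profiled at ``bmdl_levels`` only."""
    out = {}
    for bmr in bmr_levels:
        bmd = compute_bmd(fit, bmr)
        bmdl = (
            compute_bmdl(fit, series, bmr, confidence)
            if bmr in bmdl_levels and np.isfinite(bmd)
            else float("nan")
        )
        out[round(float(bmr), 6)] = BMDEstimate(
            bmr=float(bmr), bmd=bmd, bmdl=bmdl, confidence=confidence
        )
    return out
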