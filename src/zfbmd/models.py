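"""Quantal (dichotomous) dose-response model families.

The eight standard regulatory parameterizations for binary adverse-outcome
incidence data, plus the grouped binomial log-likelihood they are fitted
under.  Each family maps a parameter vector ``theta`` and a non-negative
dose ``d`` to a response probability ``p(d) in [0, 1]``:

====================  ==========================  =============================
name                  parameters                  p(d)
====================  ==========================  =============================
logistic              a, b                        1 / (1 + exp(-(a + b d)))
probit                a, b                        Phi(a + b d)
log_logistic          g, a, b                     g + (1-g) / (1 + exp(-(a + b ln d)))
log_probit            g, a, b                     g + (1-g) Phi(a + b ln d)
gamma                 g, alpha, b                 g + (1-g) GammaCDF(b d; alpha)
weibull               g, alpha, b                 g + (1-g)(1 - exp(-b d^alpha))
multistage2           g, b1, b2                   g + (1-g)(1 - exp(-(b1 d + b2 d^2)))
quantal_linear        g, b                        g + (1-g)(1 - exp(-b d))
====================  ==========================  =============================

``g`` is the background response probability, constrained to ``[0, 1)``;
slope-type parameters are non-negative and power parameters positive, so
every family is non-decreasing in dose.  Log-dose models return ``g`` at
``d = 0`` by continuous extension (the limit as ``d -> 0+`` for positive
slope; the constant value when the slope is zero).

Exact nestings used in the test suite: ``quantal_linear`` equals ``weibull``
with ``alpha = 1`` and ``multistage2`` with ``b2 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "QuantalModel",
    "MODELS",
    "MODEL_ORDER",
    "get_model",
    "log_likelihood",
    "extra_risk",
    "P_EPS",
]

P_EPS = 1e-10  # probability clamp for likelihood evaluation

_INF = np.inf


def _safe_log_dose(d: np.ndarray) -> np.ndarray:
    """ln(d) with -inf at d == 0 (no warning)."""
    with np.errstate(divide="ignore"):
        return np.log(d)


def _logdose_linear(a: float, b: float, d: np.ndarray) -> np.ndarray:
    """a + b ln d, continuously extended at d == 0.

    For b > 0 the limit is -inf; for b == 0 the expression is the constant a.
    """
    if b == 0:
        return np.full_like(d, a, dtype=float)
    return a + b * _safe_log_dose(d)


def _p_logistic(theta, d):
    a, b = theta
    return expit(a + b * d)


def _p_probit(theta, d):
    a, b = theta
    return ndtr(a + b * d)


def _p_log_logistic(theta, d):
    g, a, b = theta
    return g + (1.0 - g) * expit(_logdose_linear(a, b, d))


def _p_log_probit(theta, d):
    g, a, b = theta
    return g + (1.0 - g) * ndtr(_logdose_linear(a, b, d))


def _p_gamma(theta, d):
    from scipy.special import gammainc

    g, alpha, b = theta
    return g + (1.0 - g) * gammainc(alpha, b * d)


def _p_weibull(theta, d):
    g, alpha, b = theta
    with np.errstate(invalid="ignore"):
        hazard = b * np.power(d, alpha)
    hazard = np.where(d == 0, 0.0, hazard)
    return g + (1.0 - g) * -np.expm1(-hazard)


def _p_multistage2(theta, d):
    g, b1, b2 = theta
    return g + (1.0 - g) * -np.expm1(-(b1 * d + b2 * d * d))


def _p_quantal_linear(theta, d):
    g, b = theta
    return g + (1.0 - g) * -np.expm1(-b * d)


# --- parameter transforms under a dose-unit change -------------------------
# _rescale(theta, c) returns theta' such that p(theta', c*d) == p(theta, d):
# the parameters equivalent to theta after every dose is multiplied by c.


def _rs_slope_last(theta, c):
    out = list(theta)
    out[-1] = out[-1] / c
    return tuple(out)


def _rs_logdose(theta, c):
    g, a, b = theta
    return (g, a - b * np.log(c), b)


def _rs_weibull(theta, c):
    g, alpha, b = theta
    return (g, alpha, b / c**alpha)


def _rs_multistage2(theta, c):
    g, b1, b2 = theta
    return (g, b1 / c, b2 / c**2)


@dataclass(frozen=True)
class QuantalModel:
    """One dichotomous dose-response family.

    ``bounds`` are the structural parameter constraints (they guarantee a
    monotone curve with p in [0, 1]); optimizers may use tighter finite
    boxes.  ``has_background`` marks families with an explicit background
    parameter ``g`` as the first component of ``theta``.
    """

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    has_background: bool
    _predict: Callable[[Sequence[float], np.ndarray], np.ndarray]
    _rescale: Callable[[Sequence[float], float], tuple]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def validate_theta(self, theta: Sequence[float]) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"{self.name} expects {self.n_params} parameters "
                f"{self.param_names}, got shape {theta.shape}"
            )
        for value, (lo, hi), pname in zip(theta, self.bounds, self.param_names):
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{self.name}: parameter {pname}={value} outside [{lo}, {hi}]"
                )
        return theta

    def predict(self, theta: Sequence[float], d) -> np.ndarray:
        """Response probability at dose(s) ``d`` (scalar or array, d >= 0)."""
        theta = self.validate_theta(theta)
        d_arr = np.asarray(d, dtype=float)
        if np.any(d_arr < 0):
            raise ValueError("doses must be non-negative")
        p = self._predict(tuple(theta), d_arr)
        p = np.clip(p, 0.0, 1.0)
        if np.isscalar(d) or d_arr.ndim == 0:
            return float(p)
        return p

    def rescale(self, theta: Sequence[float], c: float) -> np.ndarray:
        """Parameters equivalent to ``theta`` after doses are multiplied by ``c``."""
        if c <= 0:
            raise ValueError("dose scale factor must be positive")
        theta = self.validate_theta(theta)
        return np.asarray(self._rescale(tuple(theta), float(c)), dtype=float)

    def param_dict(self, theta: Sequence[float]) -> Mapping[str, float]:
        theta = self.validate_theta(theta)
        return dict(zip(self.param_names, map(float, theta)))


_G = (0.0, 1.0 - 1e-9)
_POS = (0.0, _INF)
_ALPHA = (1e-9, _INF)
_A = (-_INF, _INF)

# Canonical order: simplest families first; used as the final tie-break in
# model selection and for deterministic iteration.
MODELS: dict[str, QuantalModel] = {
    m.name: m
    for m in [
        QuantalModel("quantal_linear", ("g", "b"), (_G, _POS), True,
                     _p_quantal_linear, _rs_slope_last),
        QuantalModel("logistic", ("a", "b"), (_A, _POS), False,
                     _p_logistic, _rs_slope_last),
        QuantalModel("probit", ("a", "b"), (_A, _POS), False,
                     _p_probit, _rs_slope_last),
        QuantalModel("multistage2", ("g", "b1", "b2"), (_G, _POS, _POS), True,
                     _p_multistage2, _rs_multistage2),
        QuantalModel("weibull", ("g", "alpha", "b"), (_G, _ALPHA, _POS), True,
                     _p_weibull, _rs_weibull),
        QuantalModel("gamma", ("g", "alpha", "b"), (_G, _ALPHA, _POS), True,
                     _p_gamma, _rs_slope_last),
        QuantalModel("log_logistic", ("g", "a", "b"), (_G, _A, _POS), True,
                     _p_log_logistic, _rs_logdose),
        QuantalModel("log_probit", ("g", "a", "b"), (_G, _A, _POS), True,
                     _p_log_probit, _rs_logdose),
    ]
}

MODEL_ORDER: tuple[str, ...] = tuple(MODELS)


def get_model(name: str) -> QuantalModel:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown quantal model {name!r}; choose from {list(MODELS)}"
        ) from None


def log_likelihood(model, theta, dose, affected, trials) -> float:
    """Grouped binomial log-likelihood.

    LL = sum_i [ y_i ln p_i + (n_i - y_i) ln(1 - p_i) ] with p_i clamped to
    [P_EPS, 1 - P_EPS].  The binomial coefficient is omitted (constant in
    theta), matching the usual convention for likelihood optimization.
    """
    if isinstance(model, str):
        model = get_model(model)
    d = np.asarray(dose, dtype=float)
    y = np.asarray(affected, dtype=float)
    n = np.asarray(trials, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("affected counts must satisfy 0 <= y <= n")
    p = np.clip(model.predict(theta, d), P_EPS, 1.0 - P_EPS)
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def extra_risk(model, theta, d) -> np.ndarray:
    """Background-adjusted incidence increase (p(d) - p(0)) / (1 - p(0))."""
    if isinstance(model, str):
        model = get_model(model)
    p0 = model.predict(theta, 0.0)
    p0 = min(p0, 1.0 - 1e-12)
    return (model.predict(theta, d) - p0) / (1.0 - p0)
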