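"""Maximum-likelihood fitting, diagnostics, and AIC model selection.

The eight quantal families are fitted to grouped binomial dose-response
data by bounded multi-start quasi-Newton optimization of the binomial
log-likelihood.  Doses are normalized internally by the series maximum, so
the optimization is identical under a change of dose units; fitted
parameters are converted back per family.

The fit/predict surface is exposed as scikit-learn-style estimators:

* :class:`QuantalCurve` — one family; ``fit(X, y, sample_weight)`` with X
  the doses, y the fraction of affected embryos per group and
  ``sample_weight`` the number of wells (trials) per group.
* :class:`QuantalCurveSelector` — fits every family and keeps the
  converged fit with the lowest AIC.

``fit_model`` / ``select_model`` / ``flatness_test`` are the thin
functional wrappers the pipeline uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaincinv, logit, ndtri
from sklearn.base import BaseEstimator

from .models import MODELS, MODEL_ORDER, P_EPS, get_model
from .preprocess import DoseResponseSeries
from .qc_gate import QCRecord

__all__ = [
    "ModelFit",
    "QuantalCurve",
    "QuantalCurveSelector",
    "fit_quantal",
    "fit_model",
    "fit_all_models",
    "flatness_test",
    "select_model",
]

# optimizer boxes in normalized dose units (doses scaled into [0, 1])
_G_BOX = (0.0, 0.999)
_FIT_BOUNDS: dict[str, tuple[tuple[float, float], ...]] = {
    "quantal_linear": (_G_BOX, (0.0, 700.0)),
    "logistic": ((-18.0, 18.0), (0.0, 100.0)),
    "probit": ((-8.0, 8.0), (0.0, 40.0)),
    "multistage2": (_G_BOX, (0.0, 700.0), (0.0, 700.0)),
    "weibull": (_G_BOX, (1e-3, 18.0), (0.0, 700.0)),
    "gamma": (_G_BOX, (1e-3, 18.0), (0.0, 700.0)),
    "log_logistic": (_G_BOX, (-40.0, 40.0), (0.0, 40.0)),
    "log_probit": (_G_BOX, (-20.0, 20.0), (0.0, 20.0)),
}

# deterministic start grid per family (normalized dose units)
_START_GRID: dict[str, list[tuple[float, ...]]] = {
    "quantal_linear": [(0.05, 1.0), (0.1, 3.0), (0.01, 0.3), (0.05, 10.0), (0.2, 0.05)],
    "logistic": [(-2.0, 5.0), (-4.0, 10.0), (-1.0, 2.0), (-3.0, 20.0), (0.0, 0.5)],
    "probit": [(-1.0, 3.0), (-2.0, 6.0), (-0.5, 1.0), (-1.5, 8.0), (0.0, 0.3)],
    "multistage2": [(0.05, 1.0, 0.0), (0.1, 2.0, 1.0), (0.01, 0.3, 0.3),
                    (0.05, 0.0, 3.0), (0.2, 5.0, 0.0)],
    "weibull": [(0.05, 1.0, 2.0), (0.1, 2.0, 4.0), (0.01, 0.7, 0.5),
                (0.05, 3.0, 8.0), (0.2, 1.0, 0.3)],
    "gamma": [(0.05, 1.0, 2.0), (0.1, 2.0, 5.0), (0.01, 0.7, 0.5),
              (0.05, 4.0, 10.0), (0.2, 1.0, 0.3)],
    "log_logistic": [(0.05, 1.0, 1.0), (0.1, 2.0, 2.0), (0.01, 0.0, 0.5),
                     (0.05, 3.0, 3.0), (0.2, 0.5, 1.5)],
    "log_probit": [(0.05, 0.5, 0.5), (0.1, 1.0, 1.0), (0.01, 0.0, 0.3),
                   (0.05, 1.5, 1.5), (0.2, 0.3, 0.8)],
}

_OPT_OPTIONS = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}


@dataclass
class ModelFit:
    """A converged (or attempted) fit of one quantal family.

    ``theta`` is the parameter vector in the internal normalized-dose
    parameterization (doses divided by ``dose_scale``); ``params`` converts
    back to the input dose units.  ``aic = 2k - 2 LL`` with k the family's
    parameter count; ``chi2`` equals the sum of squared scaled residuals.
    """

    model: str
    theta: np.ndarray
    dose_scale: float
    loglik: float
    aic: float
    chi2: float
    p_fit: float
    df: int
    scaled_residuals: np.ndarray
    converged: bool
    n_params: int

    @property
    def spec(self):
        return get_model(self.model)

    @property
    def params(self) -> Mapping[str, float]:
        """Fitted parameters expressed in the input dose units."""
        natural = self.spec.rescale(self.theta, self.dose_scale)
        return self.spec.param_dict(natural)

    def predict(self, d) -> np.ndarray:
        """Fitted response probability at dose(s) ``d`` in input units."""
        return self.spec.predict(self.theta, np.asarray(d, dtype=float) / self.dose_scale)


def _nll_factory(spec, u, y, n):
    predict = spec._predict

    def nll(theta):
        p = np.clip(predict(tuple(theta), u), P_EPS, 1.0 - P_EPS)
        return -float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))

    return nll


def _data_driven_start(name: str, u, y, n) -> tuple[float, ...]:
    f = y / n
    f0 = float(f[u == u.min()][0])
    fmax = float(f.max())
    g0 = float(np.clip(f0, 1e-3, 0.8))
    risk = float(np.clip((fmax - g0) / (1.0 - g0), 0.05, 0.95))
    a_lin = -np.log1p(-risk)
    nz = u[u > 0]
    u_half = float(np.median(nz)) if nz.size else 0.5
    if name == "quantal_linear":
        return (g0, a_lin)
    if name == "multistage2":
        return (g0, a_lin, 0.0)
    if name == "weibull":
        return (g0, 1.0, a_lin)
    if name == "gamma":
        return (g0, 1.0, a_lin)
    if name == "logistic":
        a = float(logit(np.clip(f0, 0.01, 0.9)))
        b = max(float(logit(np.clip(fmax, 0.02, 0.99))) - a, 0.1)
        return (a, b)
    if name == "probit":
        a = float(ndtri(np.clip(f0, 0.01, 0.9)))
        b = max(float(ndtri(np.clip(fmax, 0.02, 0.99))) - a, 0.1)
        return (a, b)
    if name == "log_logistic":
        return (g0, -np.log(u_half), 1.0)
    if name == "log_probit":
        return (g0, -0.7 * np.log(u_half), 0.7)
    raise KeyError(name)


def _clip_to_bounds(theta, bounds):
    return tuple(
        float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(theta, bounds)
    )


def fit_quantal(
    model: str,
    dose: Sequence[float],
    affected: Sequence[float],
    trials: Sequence[float],
    *,
    seed: int = 0,
    n_jitter: int = 5,
    restrict_power: bool = False,
    fix: Mapping[str, float] | None = None,
) -> ModelFit:
    """Fit one quantal family to grouped counts by multi-start MLE.

    Starts are a fixed deterministic grid plus one data-driven start plus
    ``n_jitter`` seeded log-normal perturbations; the best optimum over all
    starts is kept and ``converged`` records whether any start satisfied
    the optimizer's tolerances.  ``fix`` pins named parameters (useful for
    nesting checks, e.g. Weibull with alpha = 1); pinning is applied in the
    normalized-dose parameterization, so only unit-free parameters (g,
    alpha) should be pinned.
    """
    spec = get_model(model)
    d = np.asarray(dose, dtype=float)
    y = np.asarray(affected, dtype=float)
    n = np.asarray(trials, dtype=float)
    if np.any(n < 1):
        raise ValueError("every dose group needs at least one well")

    scale = float(d.max()) if d.max() > 0 else 1.0
    u = d / scale

    bounds = [list(b) for b in _FIT_BOUNDS[model]]
    if restrict_power and "alpha" in spec.param_names:
        i = spec.param_names.index("alpha")
        bounds[i][0] = max(bounds[i][0], 1.0)
    for pname, value in (fix or {}).items():
        i = spec.param_names.index(pname)
        bounds[i] = [float(value), float(value)]
    bounds = [tuple(b) for b in bounds]

    data_start = _clip_to_bounds(_data_driven_start(model, u, y, n), bounds)
    starts = [data_start]
    starts += [_clip_to_bounds(s, bounds) for s in _START_GRID[model]]
    rng = np.random.default_rng(seed)
    base = np.asarray(data_start, dtype=float)
    for _ in range(n_jitter):
        jit = base * rng.lognormal(0.0, 0.5, size=base.size) + rng.normal(0, 0.1, base.size)
        starts.append(_clip_to_bounds(jit, bounds))

    nll = _nll_factory(spec, u, y, n)
    best = None
    any_success = False
    n_replicated = 0
    seen = set()
    for x0 in starts:
        key = tuple(np.round(x0, 12))
        if key in seen:
            continue
        seen.add(key)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds, options=_OPT_OPTIONS
            )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-9:
            best = res
            n_replicated = 0
        elif res.fun <= best.fun + 1e-6:
            n_replicated += 1
        any_success = any_success or bool(res.success)
        # the optimum has been independently replicated: stop restarting
        if any_success and n_replicated >= 2:
            break

    # polish from the best point with a tighter tolerance
    if best is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            polish = optimize.minimize(
                nll, best.x, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10},
            )
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            best = polish
            any_success = any_success or bool(polish.success)

    if best is None:
        theta = np.asarray(starts[0], dtype=float)
        ll = -nll(theta)
        converged = False
    else:
        theta = np.asarray(best.x, dtype=float)
        ll = -float(best.fun)
        converged = any_success

    k = spec.n_params
    p_hat = np.clip(spec.predict(theta, u), P_EPS, 1.0 - P_EPS)
    resid = (y - n * p_hat) / np.sqrt(n * p_hat * (1.0 - p_hat))
    chi2_stat = float(np.sum(resid**2))
    df = max(len(u) - k, 1)
    p_fit = float(stats.chi2.sf(chi2_stat, df))

    return ModelFit(
        model=model,
        theta=theta,
        dose_scale=scale,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        chi2=chi2_stat,
        p_fit=p_fit,
        df=df,
        scaled_residuals=resid,
        converged=converged,
        n_params=k,
    )


class QuantalCurve(BaseEstimator):
    """Scikit-learn-style quantal dose-response curve for one family.

    Parameters
    ----------
    model : family name (see ``zfbmd.models.MODELS``).
    n_jitter : number of seeded random restarts added to the deterministic
        start grid.
    restrict_power : constrain power parameters (alpha) to >= 1.
    fix : mapping of parameter name to pinned value (normalized-dose
        parameterization; pin only unit-free parameters).
    random_state : seed for the jittered restarts.

    Attributes (after ``fit``)
    --------------------------
    params_ : fitted parameters in input dose units.
    loglik_, aic_, chi2_, chi2_pvalue_, scaled_residuals_, converged_,
    dose_scale_, fit_ : the underlying :class:`ModelFit`.
    """

    def __init__(self, model="quantal_linear", n_jitter=5, restrict_power=False,
                 fix=None, random_state=0):
        self.model = model
        self.n_jitter = n_jitter
        self.restrict_power = restrict_power
        self.fix = fix
        self.random_state = random_state

    @staticmethod
    def _dose_vector(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be doses: shape (n,) or (n, 1)")
            X = X[:, 0]
        if np.any(X < 0):
            raise ValueError("doses must be non-negative")
        return X

    def fit(self, X, y, sample_weight=None):
        """Fit to dose groups.

        X : doses, shape (n_groups,) or (n_groups, 1).
        y : fraction of affected embryos per group, in [0, 1].
        sample_weight : wells (binomial trials) per group; defaults to 1.
        """
        d = self._dose_vector(X)
        f = np.asarray(y, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("y must be fractions in [0, 1]")
        n = (np.ones_like(d) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        affected = f * n
        self.fit_ = fit_quantal(
            self.model, d, affected, n,
            seed=self.random_state, n_jitter=self.n_jitter,
            restrict_power=self.restrict_power, fix=self.fix,
        )
        self.params_ = dict(self.fit_.params)
        self.theta_ = self.fit_.theta.copy()
        self.dose_scale_ = self.fit_.dose_scale
        self.loglik_ = self.fit_.loglik
        self.aic_ = self.fit_.aic
        self.chi2_ = self.fit_.chi2
        self.chi2_pvalue_ = self.fit_.p_fit
        self.scaled_residuals_ = self.fit_.scaled_residuals.copy()
        self.converged_ = self.fit_.converged
        self.n_params_ = self.fit_.n_params
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted response probability at the given doses."""
        return self.fit_.predict(self._dose_vector(X))

    def score(self, X, y, sample_weight=None) -> float:
        """Mean per-trial binomial log-likelihood (higher is better)."""
        d = self._dose_vector(X)
        f = np.asarray(y, dtype=float)
        n = (np.ones_like(d) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        p = np.clip(self.fit_.predict(d), P_EPS, 1.0 - P_EPS)
        ll = np.sum(n * (f * np.log(p) + (1.0 - f) * np.log1p(-p)))
        return float(ll / n.sum())


class QuantalCurveSelector(BaseEstimator):
    """Fit all quantal families and keep the converged fit with lowest AIC.

    Ties are broken by fewer parameters, then by the canonical family
    order.  After ``fit``: ``best_model_``, ``best_fit_``, ``fits_`` (all
    attempted fits, by name), ``aic_`` of the winner.
    """

    def __init__(self, models=None, n_jitter=5, restrict_power=False, random_state=0):
        self.models = models
        self.n_jitter = n_jitter
        self.restrict_power = restrict_power
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        names = tuple(self.models) if self.models is not None else MODEL_ORDER
        d = QuantalCurve._dose_vector(X)
        f = np.asarray(y, dtype=float)
        n = (np.ones_like(d) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        self.fits_ = {
            name: fit_quantal(
                name, d, f * n, n, seed=self.random_state,
                n_jitter=self.n_jitter, restrict_power=self.restrict_power,
            )
            for name in names
        }
        converged = [m for m in self.fits_.values() if m.converged]
        if not converged:
            raise RuntimeError("no quantal family converged")
        self.best_fit_ = min(converged, key=_selection_key)
        self.best_model_ = self.best_fit_.model
        self.aic_ = self.best_fit_.aic
        return self

    def predict(self, X) -> np.ndarray:
        return self.best_fit_.predict(QuantalCurve._dose_vector(X))


def _selection_key(fit: ModelFit):
    return (fit.aic, fit.n_params, MODEL_ORDER.index(fit.model))


def _series_seed(series: DoseResponseSeries, base_seed: int) -> int:
    import zlib

    tag = f"{series.substance_id}|{series.endpoint}".encode()
    return int((zlib.crc32(tag) ^ (base_seed & 0xFFFFFFFF)) & 0x7FFFFFFF)


def fit_model(model: str, series: DoseResponseSeries, config) -> ModelFit:
    """Fit one family to a series (pipeline wrapper around ``fit_quantal``).

    A series with fewer than two non-control groups cannot identify a
    curve; the fit is declined and reported as non-converged.
    """
    fit = None
    if int(np.sum(series.d > 0)) < 2:
        fit = fit_quantal(model, series.d, series.y, series.n, n_jitter=0)
        fit.converged = False
        return fit
    return fit_quantal(
        model, series.d, series.y, series.n,
        seed=_series_seed(series, config.seed),
        restrict_power=config.restrict_power,
    )


def fit_all_models(series: DoseResponseSeries, config, models=None) -> list[ModelFit]:
    """Fit the requested families (default: all eight) to one series."""
    names = tuple(models) if models is not None else MODEL_ORDER
    return [fit_model(name, series, config) for name in names]


def flatness_test(series: DoseResponseSeries) -> float:
    """Two-sided one-sample t-test on consecutive response differences.

    With groups sorted by dose, Delta_i = f_{i+1} - f_i; the p-value tests
    mean(Delta) = 0.  A non-flat monotone series has same-signed
    differences and a small p.  Degenerate cases: zero variance with zero
    mean -> p = 1 (flat); zero variance with nonzero mean -> p = 0 (a
    perfectly regular trend), with a warning.
    """
    diffs = np.diff(series.f)
    if diffs.size < 2:
        raise ValueError("flatness test needs at least 3 dose groups")
    m = float(np.mean(diffs))
    s = float(np.std(diffs, ddof=1))
    if s <= 1e-12:  # zero within-sample variance up to float noise
        if abs(m) <= 1e-12:
            return 1.0
        warnings.warn(
            "flatness test: zero variance with nonzero mean difference; p set to 0",
            stacklevel=2,
        )
        return 0.0
    t = m / (s / np.sqrt(diffs.size))
    return float(2.0 * stats.t.sf(abs(t), df=diffs.size - 1))


def select_model(
    fits: Sequence[ModelFit], series: DoseResponseSeries, config
) -> tuple[ModelFit | None, QCRecord]:
    """Pick the converged fit with lowest AIC and score the curve.

    Score is Good when the flatness-test p-value is at or below
    ``config.flat_p_cutoff`` (default 0.32), else Moderate.  With no
    converged fit the series is demoted to Poor with reason fit_failed.
    """
    converged = [m for m in fits if m.converged]
    if not converged:
        return None, QCRecord(score="Poor", reason="fit_failed")
    chosen = min(converged, key=_selection_key)
    p_flat = flatness_test(series)
    score = "Good" if p_flat <= config.flat_p_cutoff else "Moderate"
    return chosen, QCRecord(score=score, reason="ok", flat_p=p_flat)
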