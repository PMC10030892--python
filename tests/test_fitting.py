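"""Maximum-likelihood fitting, diagnostics, flatness test, model selection."""

import dataclasses
import math

import numpy as np
import pytest
from sklearn.base import clone

from zfbmd import PipelineConfig
from zfbmd.fitting import (
    ModelFit,
    QuantalCurve,
    QuantalCurveSelector,
    fit_all_models,
    fit_model,
    fit_quantal,
    flatness_test,
    select_model,
)
from zfbmd.models import MODEL_ORDER, get_model
from zfbmd.qc_gate import gate

from conftest import make_series


def exact_counts_series(model, theta, d, n):
    """Counts placed exactly on the model curve (rounded to integers)."""
    p = get_model(model).predict(theta, np.asarray(d, float))
    f = np.round(np.asarray(p) * n) / n
    return make_series(d, f, n=n)


class TestFitQuantal:
    def test_recovers_slope_on_exact_large_n_data(self):
        """Data on a quantal-linear curve at n=10000/group pins b to 2%."""
        series = exact_counts_series(
            "quantal_linear", (0.05, 0.05), [0, 1.5, 6, 25, 50], 10000
        )
        fit = fit_quantal("quantal_linear", series.d, series.y, series.n, seed=0)
        assert fit.converged
        assert fit.params["b"] == pytest.approx(0.05, rel=0.02)
        assert fit.params["g"] == pytest.approx(0.05, abs=0.01)

    def test_flat_data_gives_flat_weibull_curve(self):
        series = make_series([0, 1, 5, 10, 20], [0.25] * 5, n=32)
        fit = fit_quantal("weibull", series.d, series.y, series.n, seed=0)
        p = fit.predict(series.d)
        np.testing.assert_allclose(p, 0.25, atol=1e-3)

    def test_chi2_equals_sum_of_squared_scaled_residuals(self, monotone_series):
        for name in MODEL_ORDER:
            fit = fit_quantal(name, monotone_series.d, monotone_series.y,
                              monotone_series.n, seed=0)
            assert fit.chi2 == pytest.approx(
                float(np.sum(fit.scaled_residuals**2)), abs=1e-9
            )

    def test_aic_identity(self, monotone_series):
        for name in MODEL_ORDER:
            fit = fit_quantal(name, monotone_series.d, monotone_series.y,
                              monotone_series.n, seed=0)
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.loglik, abs=1e-9
            )

    def test_seed_only_perturbs_theta_below_tolerance(self, monotone_series):
        """Multi-start makes the optimum jitter-seed independent."""
        f1 = fit_quantal("quantal_linear", monotone_series.d, monotone_series.y,
                         monotone_series.n, seed=1)
        f2 = fit_quantal("quantal_linear", monotone_series.d, monotone_series.y,
                         monotone_series.n, seed=99)
        np.testing.assert_allclose(f1.theta, f2.theta, atol=1e-4)

    def test_single_nonzero_dose_declined(self, config):
        series = make_series([0, 5], [0.1, 0.6])
        fit = fit_model("quantal_linear", series, config)
        assert not fit.converged

    def test_pinned_alpha_reproduces_quantal_linear(self, monotone_series):
        ql = fit_quantal("quantal_linear", monotone_series.d, monotone_series.y,
                         monotone_series.n, seed=0)
        wb = fit_quantal("weibull", monotone_series.d, monotone_series.y,
                         monotone_series.n, seed=0, fix={"alpha": 1.0})
        assert wb.loglik == pytest.approx(ql.loglik, abs=1e-6)


class TestEstimators:
    def test_quantal_curve_sklearn_contract(self, monotone_series):
        est = QuantalCurve(model="quantal_linear", random_state=0)
        cloned = clone(est)
        assert cloned.get_params()["model"] == "quantal_linear"
        est.fit(monotone_series.d.reshape(-1, 1), monotone_series.f,
                sample_weight=monotone_series.n)
        assert est.converged_
        assert set(est.params_) == {"g", "b"}
        p = est.predict([0.0, 10.0])
        assert p.shape == (2,) and np.all((p >= 0) & (p <= 1))
        assert est.score(monotone_series.d, monotone_series.f,
                         monotone_series.n) <= 0.0

    def test_selector_picks_lowest_aic(self, monotone_series):
        sel = QuantalCurveSelector(random_state=0).fit(
            monotone_series.d, monotone_series.f, sample_weight=monotone_series.n
        )
        best_aic = min(f.aic for f in sel.fits_.values() if f.converged)
        assert sel.aic_ == best_aic
        assert sel.best_fit_.model == sel.best_model_

    def test_rejects_invalid_inputs(self):
        est = QuantalCurve()
        with pytest.raises(ValueError):
            est.fit([[1.0, 2.0]], [0.5])  # two columns
        with pytest.raises(ValueError):
            est.fit([1.0], [1.5])  # fraction out of range


class TestFlatness:
    def test_uniform_steps_give_zero_p_with_warning(self):
        series = make_series([0, 1, 2, 3], [0.1, 0.2, 0.3, 0.4], n=10)
        with pytest.warns(UserWarning, match="zero variance"):
            assert flatness_test(series) == 0.0

    def test_flat_series_gives_p_one(self):
        series = make_series([0, 1, 2, 3], [0.2, 0.2, 0.2, 0.2], n=10)
        assert flatness_test(series) == 1.0

    def test_matches_hand_computed_t_statistic(self):
        # f = (0.0, 0.3, 0.2, 0.6): diffs (0.3, -0.1, 0.4)
        series = make_series([0, 1, 2, 3], [0.0, 0.3, 0.2, 0.6], n=10)
        diffs = [0.3, -0.1, 0.4]
        m = sum(diffs) / 3
        sd = math.sqrt(sum((x - m) ** 2 for x in diffs) / 2)
        t = m / (sd / math.sqrt(3))
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(t), df=2)
        assert flatness_test(series) == pytest.approx(expected, abs=1e-12)

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            flatness_test(make_series([0, 1], [0.1, 0.2]))


def test_generating_family_aic_close_to_winner_at_large_n():
    """With ample data the true family's AIC trails the selected model's by
    at most 2 in most replicates (nesting keeps exact wins non-guaranteed)."""
    rng = np.random.default_rng(6)
    d = np.array([0.0, 1.5, 6.0, 25.0, 50.0])
    p = get_model("quantal_linear").predict((0.05, 0.05), d)
    config = PipelineConfig(seed=1)
    close = 0
    n_rep = 10
    for _ in range(n_rep):
        y = rng.binomial(2000, p)
        series = make_series(d, y / 2000, n=2000)
        fits = fit_all_models(series, config)
        chosen, _ = select_model(fits, series, config)
        ql_aic = next(f.aic for f in fits if f.model == "quantal_linear")
        close += ql_aic <= chosen.aic + 2.0
    assert close >= 0.8 * n_rep


def fake_fit(model, aic, k=2, converged=True):
    return ModelFit(
        model=model, theta=np.zeros(k), dose_scale=1.0, loglik=-aic / 2 + k,
        aic=aic, chi2=0.0, p_fit=1.0, df=1,
        scaled_residuals=np.zeros(3), converged=converged, n_params=k,
    )


class TestSelectModel:
    def test_lowest_aic_wins(self, config, monotone_series):
        fits = [fake_fit("logistic", 100.0), fake_fit("probit", 98.5)]
        chosen, qc = select_model(fits, monotone_series, config)
        assert chosen.model == "probit"

    def test_selection_matches_bruteforce_argmin(self, config, monotone_series):
        rng = np.random.default_rng(4)
        for _ in range(50):
            names = list(rng.permutation(MODEL_ORDER))
            aics = rng.uniform(50, 150, len(names)).round(3)
            fits = [fake_fit(nm, a) for nm, a in zip(names, aics)]
            chosen, _ = select_model(fits, monotone_series, config)
            assert chosen.aic == min(aics)

    def test_tie_broken_by_parameter_count_then_order(self, config, monotone_series):
        fits = [
            fake_fit("weibull", 90.0, k=3),
            fake_fit("quantal_linear", 90.0, k=2),
            fake_fit("logistic", 90.0, k=2),
        ]
        chosen, _ = select_model(fits, monotone_series, config)
        assert chosen.model == "quantal_linear"  # k=2, earlier canonical order

    def test_unconverged_fits_excluded(self, config, monotone_series):
        fits = [fake_fit("probit", 10.0, converged=False), fake_fit("logistic", 99.0)]
        chosen, _ = select_model(fits, monotone_series, config)
        assert chosen.model == "logistic"

    def test_no_converged_fit_is_poor(self, config, monotone_series):
        fits = [fake_fit("probit", 10.0, converged=False)]
        chosen, qc = select_model(fits, monotone_series, config)
        assert chosen is None
        assert qc.score == "Poor" and qc.reason == "fit_failed"

    def test_strong_trend_scores_good(self, config, design):
        from zfbmd import build_series, filter_control_plates, simulate_plates

        records = simulate_plates(design)
        kept, _ = filter_control_plates(records, 0.5, endpoint=design.endpoint)
        series = build_series(kept, design.substance_id, design.endpoint)
        assert gate(series, config).proceed
        fits = fit_all_models(series, config)
        chosen, qc = select_model(fits, series, config)
        assert qc.score == "Good" and qc.flat_p <= config.flat_p_cutoff

    def test_weak_trend_scores_moderate(self, config):
        # passes the Spearman gate but steps cancel -> high flatness p
        series = make_series([0, 1, 2, 3, 4], [0.20, 0.18, 0.32, 0.26, 0.33], n=32)
        assert gate(series, config).proceed
        fits = fit_all_models(series, config)
        chosen, qc = select_model(fits, series, config)
        assert qc.score == "Moderate" and qc.flat_p > config.flat_p_cutoff
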