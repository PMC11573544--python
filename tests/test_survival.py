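"""Parametric families: closed forms, MLE recovery, AIC selection, medians."""

import math

import numpy as np
import pytest
from lifelines import LogLogisticFitter, LogNormalFitter

from uccea import (FAMILIES, FitResult, fit_all, fit_mle, median_survival,
                   select_by_aic, simulate_ipd, survival)
from uccea.ipd import IPD
from uccea.survival import loglik

_REF_PARAMS = {
    "exponential": {"rate": 0.05},
    "weibull": {"shape": 1.4, "scale": 20.0},
    "lognormal": {"mu": 2.5, "sigma": 0.8},
    "loglogistic": {"alpha": 18.0, "beta": 1.8},
    "gompertz": {"shape": 0.03, "rate": 0.02},
}


class TestSurvivalFunction:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_s0_is_one_monotone_bounded(self, family):
        t = np.linspace(0.0, 120.0, 600)
        s = survival(family, _REF_PARAMS[family], t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))

    def test_loglogistic_median_identity(self):
        for beta in (0.7, 1.5, 4.0):
            assert survival("loglogistic", {"alpha": 9.3, "beta": beta},
                            9.3) == pytest.approx(0.5)

    def test_weibull_scale_point(self):
        s = survival("weibull", {"shape": 1.0, "scale": 20.0}, 20.0)
        assert s == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            survival("weibull", {"shape": -1.0, "scale": 20.0}, 1.0)
        with pytest.raises(ValueError, match="supported"):
            survival("gamma", {"shape": 1.0}, 1.0)


class TestFitMLE:
    def test_loglogistic_parameter_recovery(self):
        ipd = simulate_ipd("loglogistic", {"alpha": 21.7, "beta": 3.0}, 5000,
                           seed=3)
        fit = fit_mle(ipd, "loglogistic")
        assert fit.converged
        assert fit.params["alpha"] == pytest.approx(21.7, rel=0.05)
        assert fit.params["beta"] == pytest.approx(3.0, rel=0.05)

    def test_exponential_closed_form_mle(self):
        ipd = simulate_ipd("exponential", {"rate": 0.1}, 5000, seed=4)
        fit = fit_mle(ipd, "exponential")
        assert fit.params["rate"] == pytest.approx(1.0 / ipd.times.mean(),
                                                   rel=1e-6)

    def test_weibull_nests_exponential(self):
        ipd = simulate_ipd("exponential", {"rate": 0.1}, 5000, seed=5)
        fit = fit_mle(ipd, "weibull")
        assert fit.params["shape"] == pytest.approx(1.0, rel=0.05)

    def test_all_censored_raises_no_events(self):
        ipd = IPD(np.linspace(1, 10, 20), np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="no events"):
            fit_mle(ipd, "weibull")

    def test_too_few_records_raises(self):
        ipd = IPD(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        with pytest.raises(ValueError):
            fit_mle(ipd, "weibull")

    def test_aic_definition(self):
        ipd = simulate_ipd("weibull", {"shape": 1.5, "scale": 10.0}, 500, seed=6)
        fit = fit_mle(ipd, "weibull")
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_mle_beats_random_admissible_points(self):
        """Log-likelihood at the optimum dominates 100 random points."""
        ipd = simulate_ipd("loglogistic", {"alpha": 12.0, "beta": 2.0}, 800,
                           censor_rate=0.2, max_follow_up=40.0, seed=7)
        fit = fit_mle(ipd, "loglogistic")
        rng = np.random.default_rng(0)
        for _ in range(100):
            params = {"alpha": rng.uniform(1, 60), "beta": rng.uniform(0.2, 8)}
            assert loglik("loglogistic", params, ipd.times, ipd.events) \
                <= fit.loglik + 1e-9

    def test_matches_lifelines_fitters(self):
        """Independent MLE cross-check on censored data."""
        ipd = simulate_ipd("loglogistic", {"alpha": 15.0, "beta": 2.5}, 2000,
                           censor_rate=0.2, max_follow_up=40.0, seed=11)
        ours = fit_mle(ipd, "loglogistic")
        ref = LogLogisticFitter().fit(ipd.times, ipd.events)
        assert ours.params["alpha"] == pytest.approx(ref.alpha_, rel=1e-4)
        assert ours.params["beta"] == pytest.approx(ref.beta_, rel=1e-4)
        assert ours.loglik == pytest.approx(ref.log_likelihood_, abs=1e-3)

        ipd2 = simulate_ipd("lognormal", {"mu": 2.0, "sigma": 0.7}, 2000,
                            censor_rate=0.2, max_follow_up=40.0, seed=12)
        ours2 = fit_mle(ipd2, "lognormal")
        ref2 = LogNormalFitter().fit(ipd2.times, ipd2.events)
        assert ours2.params["mu"] == pytest.approx(ref2.mu_, rel=1e-4)
        assert ours2.params["sigma"] == pytest.approx(ref2.sigma_, rel=1e-4)


class TestSelectByAIC:
    def test_single_converged_fit_returned(self):
        fit = FitResult("weibull", {"shape": 1.0, "scale": 2.0}, -10.0, 24.0,
                        100, True)
        assert select_by_aic([fit]) is fit

    def test_equal_aic_fewer_params_wins(self):
        f1 = FitResult("exponential", {"rate": 0.1}, -10.0, 50.0, 100, True)
        f2 = FitResult("weibull", {"shape": 1.0, "scale": 10.0}, -10.0, 50.0,
                       100, True)
        assert select_by_aic([f2, f1]).family == "exponential"

    def test_no_converged_fit_raises(self):
        bad = FitResult("weibull", {}, math.nan, math.nan, 100, False)
        with pytest.raises(ValueError, match="converged"):
            select_by_aic([bad])

    def test_generating_family_usually_selected(self):
        """AIC prefers the generating family in most seeded replicates."""
        wins = 0
        for rep in range(10):
            ipd = simulate_ipd("loglogistic", {"alpha": 10.0, "beta": 2.0},
                               2000, censor_rate=0.2, max_follow_up=40.0,
                               seed=200 + rep)
            wins += select_by_aic(fit_all(ipd)).family == "loglogistic"
        assert wins >= 8


class TestMedianSurvival:
    def test_closed_forms(self):
        assert median_survival(
            FitResult.from_params("loglogistic", {"alpha": 21.7, "beta": 1.3})
        ) == pytest.approx(21.7)
        lam = math.log(2) / 18.9
        assert median_survival(
            FitResult.from_params("exponential", {"rate": lam})
        ) == pytest.approx(18.9)
        assert median_survival(
            FitResult.from_params("lognormal", {"mu": math.log(7.9), "sigma": 1.0})
        ) == pytest.approx(7.9)

    def test_gompertz_median_matches_grid_search(self):
        fit = FitResult.from_params("gompertz", {"shape": 0.05, "rate": 0.01})
        grid = np.arange(1e-4, 200.0, 1e-4)
        s = survival("gompertz", fit.params, grid)
        brute = grid[np.argmin(np.abs(s - 0.5))]
        assert median_survival(fit) == pytest.approx(brute, abs=1e-3)

    def test_unreachable_median_raises(self):
        fit = FitResult.from_params("exponential", {"rate": 1e-9})
        with pytest.raises(ValueError, match="0.5"):
            median_survival(fit, t_max=1e6)
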