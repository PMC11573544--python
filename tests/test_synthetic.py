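"""Generator calibration, IPD simulation, curve emulation, life table."""

import numpy as np
import pytest

from uccea import (CHECKMATE_901, TrialCalibration, calibrate_family,
                   emulate_digitized_curve, make_life_table, simulate_ipd)
from uccea.reconstruct import km_median
from uccea.synthetic import _quantile


class TestCalibrateFamily:
    def test_loglogistic_median_is_scale(self):
        cal = CHECKMATE_901[("nivo_combo", "OS")]
        params = calibrate_family(cal)
        assert params["alpha"] == pytest.approx(21.7)
        assert params["beta"] > 0

    def test_lognormal_median_is_exp_mu(self):
        cal = CHECKMATE_901[("nivo_combo", "PFS")]
        params = calibrate_family(cal)
        assert np.exp(params["mu"]) == pytest.approx(7.9)

    def test_unsupported_family_names_supported_set(self):
        with pytest.raises(ValueError, match="loglogistic"):
            TrialCalibration("gem_cis", "OS", 18.9, 14.7, 22.4, "weibull")

    def test_ci_width_recovered_by_monte_carlo(self):
        """Sampling spread of the KM median at n=300 reproduces the printed
        CI width within 30% (10,000 uncensored replicates)."""
        cal = CHECKMATE_901[("gem_cis", "OS")]
        params = calibrate_family(cal, reference_n=300)
        rng = np.random.default_rng(42)
        u = rng.random((10_000, 300))
        t = _quantile("loglogistic", params, u)
        medians = np.median(t, axis=1)  # uncensored KM median = sample median
        width = np.quantile(medians, 0.975) - np.quantile(medians, 0.025)
        target = cal.ci_high_months - cal.ci_low_months
        assert 0.7 <= width / target <= 1.3

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            TrialCalibration("gem_cis", "OS", 18.9, 22.0, 22.4, "loglogistic")


class TestSimulateIPD:
    def test_seeded_runs_identical(self):
        a = simulate_ipd("loglogistic", {"alpha": 21.7, "beta": 1.3}, 100, seed=7)
        b = simulate_ipd("loglogistic", {"alpha": 21.7, "beta": 1.3}, 100, seed=7)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.events, b.events)

    def test_exponential_mean_matches_closed_form(self):
        # rate 0.1/month embedded as Weibull shape 1 => mean 10 months
        ipd = simulate_ipd("weibull", {"shape": 1.0, "scale": 10.0}, 50_000, seed=3)
        assert ipd.times.mean() == pytest.approx(10.0, rel=0.02)

    def test_loglogistic_median_matches_closed_form(self):
        ipd = simulate_ipd("loglogistic", {"alpha": 21.7, "beta": 1.26}, 50_000,
                           seed=5)
        assert np.median(ipd.times) == pytest.approx(21.7, rel=0.015)

    def test_censoring_bounds_and_flags(self):
        ipd = simulate_ipd("loglogistic", {"alpha": 21.7, "beta": 1.3}, 2000,
                           censor_rate=0.3, max_follow_up=36.0, seed=9)
        assert ipd.times.max() <= 36.0
        assert 0 < ipd.n_events < len(ipd)
        # administrative censoring: nobody observed beyond follow-up as event
        assert np.all(ipd.times[ipd.events == 0] <= 36.0)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_censor_rate_domain(self, bad):
        with pytest.raises(ValueError):
            simulate_ipd("weibull", {"shape": 1.0, "scale": 10.0}, 10,
                         censor_rate=bad, max_follow_up=10.0)


class TestEmulateDigitizedCurve:
    def test_no_jitter_reads_equal_km_steps(self):
        ipd = simulate_ipd("loglogistic", {"alpha": 10.0, "beta": 2.0}, 60,
                           censor_rate=0.2, max_follow_up=30.0, seed=1)
        event_times = np.unique(ipd.times[ipd.events == 1])
        em = emulate_digitized_curve(
            "loglogistic", {"alpha": 10.0, "beta": 2.0}, event_times, n0=60,
            seed=1, jitter_sd=0.0, censor_rate=0.2, max_follow_up=30.0)
        from uccea.reconstruct import km_estimate
        np.testing.assert_allclose(em.curve.survival,
                                   km_estimate(em.ipd, event_times))

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_survival_non_increasing_any_seed(self, seed):
        em = emulate_digitized_curve("loglogistic", {"alpha": 21.7, "beta": 1.3},
                                     np.arange(0.0, 36.1, 1.0), n0=300, seed=seed)
        assert np.all(np.diff(em.curve.survival) <= 0)

    def test_emulated_km_median_within_printed_ci(self):
        cal = CHECKMATE_901[("nivo_combo", "OS")]
        params = calibrate_family(cal)
        em = emulate_digitized_curve(cal.family, params,
                                     np.arange(0.0, 36.1, 0.5), n0=300, seed=2)
        assert cal.ci_low_months <= km_median(em.ipd) <= cal.ci_high_months

    def test_flat_tail_flagged(self):
        with pytest.warns(UserWarning, match="flat"):
            em = emulate_digitized_curve("weibull", {"shape": 2.0, "scale": 5.0},
                                         np.arange(0.0, 60.1, 5.0), n0=50, seed=3,
                                         censor_rate=0.0, max_follow_up=np.inf)
        assert em.flat_tail

    def test_risk_table_counts_at_risk(self):
        em = emulate_digitized_curve("loglogistic", {"alpha": 21.7, "beta": 1.3},
                                     np.arange(0.0, 36.1, 1.0), n0=300,
                                     risk_interval=3.0, seed=4)
        assert em.risk.n_at_risk[0] == 300
        for t, n in zip(em.risk.times, em.risk.n_at_risk):
            assert n == (em.ipd.times >= t).sum()


class TestLifeTable:
    def test_null_hazard_gives_zero(self):
        lt = make_life_table(0.0, 0.0, 0.09)
        assert np.all(lt.annual_mortality == 0.0)

    def test_monotone_hazard_and_ordering(self):
        lt = make_life_table()
        assert lt.q_at(100) > lt.q_at(65) > lt.q_at(40)
        q = lt.annual_mortality
        above40 = q[lt.ages >= 40]
        assert np.all(np.diff(above40) >= 0)

    def test_default_q65_plausible(self):
        lt = make_life_table()
        assert 0.01 <= lt.q_at(65) <= 0.02

    def test_beyond_table_carries_last_row(self):
        lt = make_life_table()
        with pytest.warns(UserWarning, match="beyond"):
            assert lt.q_at(140) == lt.annual_mortality[-1]

    def test_csv_round_trip(self, tmp_path):
        lt = make_life_table()
        lt.to_csv(tmp_path / "lt.csv")
        from uccea import SyntheticLifeTable
        back = SyntheticLifeTable.from_csv(tmp_path / "lt.csv")
        np.testing.assert_allclose(back.annual_mortality, lt.annual_mortality)
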