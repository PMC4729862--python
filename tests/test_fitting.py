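"""Relaxation, recovery, superactivation, charge-transfer and Hill fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tarpgate as tg
from tarpgate import fitting as ft
from tarpgate import protocols as pr

T = np.arange(0, 0.3, 5e-5)


class TestExponentialFits:
    def test_recovers_its_own_model_class(self):
        y = 0.7 * np.exp(-100 * T) + 0.3 * np.exp(-10 * T)
        fit = tg.fit_exponentials(T, y, n_components=2)
        assert fit.rates == pytest.approx([100.0, 10.0], rel=1e-3)
        assert fit.amplitudes == pytest.approx([0.7, 0.3], rel=1e-3)
        assert fit.weighted_rate == pytest.approx(73.0, rel=1e-3)

    def test_single_component_weighted_rate_is_the_rate(self):
        y = 2.0 * np.exp(-55.0 * T) + 0.2
        fit = tg.fit_exponentials(T, y, n_components=1)
        assert fit.weighted_rate == pytest.approx(fit.rates[0])
        assert fit.weighted_rate == pytest.approx(55.0, rel=1e-4)
        assert fit.baseline == pytest.approx(0.2, abs=1e-6)

    def test_deterministic_repeats(self):
        rng = np.random.default_rng(5)
        y = np.exp(-80 * T) + 0.002 * rng.standard_normal(len(T))
        a = tg.fit_exponentials(T, y, n_components=2)
        b = tg.fit_exponentials(T, y, n_components=2)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_window_too_small_rejected(self):
        with pytest.raises(ft.FitError):
            tg.fit_exponentials(T[:15], np.exp(-10 * T[:15]), n_components=2)

    @given(st.floats(20, 2000), st.floats(0.1, 0.9))
    @settings(max_examples=15, deadline=None)
    def test_property_two_component_recovery(self, k_fast, a_fast):
        k_slow = k_fast / 8
        y = a_fast * np.exp(-k_fast * T) + (1 - a_fast) * np.exp(-k_slow * T)
        fit = tg.fit_exponentials(T, y, n_components=2, baseline="fixed")
        expected = a_fast * k_fast + (1 - a_fast) * k_slow
        assert fit.weighted_rate == pytest.approx(expected, rel=2e-2)


class TestRecoveryFits:
    intervals = np.geomspace(0.004, 0.8, 12)

    def test_exact_recovery_of_generating_model(self):
        truth = ft.RecoveryFit(22.0, 0.12, "HH")
        fit = tg.fit_recovery(self.intervals, truth(self.intervals))
        assert fit.k_rec == pytest.approx(22.0, rel=1e-6)
        assert fit.n0 == pytest.approx(0.12, abs=1e-6)

    def test_constant_responses_rejected(self):
        with pytest.raises(ft.FitError, match="constant"):
            tg.fit_recovery(self.intervals, np.ones(12))

    def test_overshoot_flagged_for_biexponential(self):
        y = 1 + 0.2 * np.exp(-2 * self.intervals)
        with pytest.raises(ft.FitError, match="overshoot"):
            tg.fit_recovery(self.intervals, y)

    def test_suprarecovery_exact_recovery(self):
        truth = ft.RecoveryFit(50.0, 0.1, "biexponential",
                               n_sup=0.15, k_sup=2.0)
        fit = tg.fit_suprarecovery(self.intervals, truth(self.intervals))
        assert fit.overshoot
        assert fit.k_rec == pytest.approx(50.0, rel=1e-4)
        assert fit.k_sup == pytest.approx(2.0, rel=1e-4)
        assert fit.n_sup == pytest.approx(0.15, rel=1e-4)

    def test_no_overshoot_falls_back_with_flag(self):
        truth = ft.RecoveryFit(22.0, 0.12, "HH")
        fit = tg.fit_suprarecovery(self.intervals, truth(self.intervals))
        assert not fit.overshoot
        assert fit.model == "HH"

    def test_nested_model_limit(self):
        # With a vanishing superactive amplitude the biexponential reduces
        # to the plain recovery fit.
        hh = ft.RecoveryFit(30.0, 0.08, "HH")
        y = hh(self.intervals) * (1 + 0.004 * np.exp(-2 * self.intervals))
        k_hh = tg.fit_recovery(self.intervals, np.clip(y, None, 1.0)).k_rec
        bi = ft.RecoveryFit(30.0, 0.08, "biexponential",
                            n_sup=0.004, k_sup=2.0)
        k_bi = tg.fit_suprarecovery(
            self.intervals, bi(self.intervals)).k_rec
        assert abs(k_bi / k_hh - 1) < 0.05


class TestSuperactivation:
    def _trace(self, current, duration=5.0):
        p = tg.make_pulse(duration, 0.01, pre=0.01, post=0.05)
        n = int(round(p.total_duration / p.sample_interval)) + 1
        t = np.arange(n) * p.sample_interval
        return pr.SimTrace(t, np.empty((n, 0)), current(t), current(t), (), p)

    def test_monotone_decay_gives_zero(self):
        trace = self._trace(lambda t: np.exp(-3 * np.clip(t - 0.01, 0, None)))
        res = tg.superactivation(trace)
        assert res.magnitude == 0.0
        assert res.rate is None

    def test_rise_after_trough_measured(self):
        def current(t):
            x = np.clip(t - 0.01, 0, None)
            return 0.5 * np.exp(-80 * x) + 0.3 * (1 - np.exp(-2 * x))
        res = tg.superactivation(self._trace(current))
        assert res.magnitude > 0
        assert res.rate == pytest.approx(2.0, rel=0.1)

    def test_short_application_rejected(self, tarp_wt):
        trace = tg.simulate(tarp_wt, tg.make_pulse(0.5, 0.01, post=0.02))
        with pytest.raises(ValueError):
            tg.superactivation(trace)


class TestChargeTransfer:
    def test_periodic_response_gives_zero(self):
        p = tg.make_train(0.001, 100.0, 12, 0.01)
        n = int(round(p.total_duration / p.sample_interval)) + 1
        t = np.arange(n) * p.sample_interval
        current = 0.5 + 0.5 * np.sin(2 * np.pi * 100 * t)
        trace = pr.SimTrace(t, np.empty((n, 0)), current, current, (), p)
        assert tg.charge_transfer_change(trace) == pytest.approx(0.0,
                                                                 abs=1e-6)

    def test_too_few_pulses_rejected(self, no_tarp_wt):
        trace = tg.simulate(no_tarp_wt, tg.make_train(0.001, 100.0, 5, 0.01))
        with pytest.raises(ValueError):
            tg.charge_transfer_change(trace)


class TestHill:
    conc = np.geomspace(1e-6, 1e-2, 9)

    def test_exact_hill_recovery(self):
        y = 3.0 / (1 + (2e-4 / self.conc) ** 1.4)
        ec50, n, top = tg.fit_hill(self.conc, y)
        assert ec50 == pytest.approx(2e-4, rel=1e-4)
        assert n == pytest.approx(1.4, rel=1e-4)
        assert top == pytest.approx(3.0, rel=1e-4)

    def test_constant_responses_rejected(self):
        with pytest.raises(ft.FitError):
            tg.fit_hill(self.conc, np.full(9, 2.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ft.FitError):
            tg.fit_hill(self.conc[:4], self.conc[:4])
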