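"""Protocol construction and master-equation simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tarpgate as tg
from tarpgate import protocols as pr


class TestProtocolBuilders:
    def test_pulse_is_three_segments(self):
        p = tg.make_pulse(0.5, 0.01)
        assert len(p.segments) == 3
        assert [s.concentration for s in p.segments] == [0.0, 0.01, 0.0]
        assert p.agonist_window() == (pytest.approx(0.01),
                                      pytest.approx(0.51))

    def test_zero_concentration_pulse_is_flat(self, no_tarp_wt):
        p = tg.make_pulse(0.5, 0.0, post=0.05)
        with pytest.raises(ValueError):
            p.agonist_window()
        trace = tg.simulate(no_tarp_wt, p)
        assert np.ptp(trace.current) < 1e-12

    def test_two_pulse_is_five_segments(self):
        p = tg.make_two_pulse(0.4, 0.2, 0.02, 0.01)
        assert len(p.segments) == 5
        concs = [s.concentration for s in p.segments]
        assert concs == [0.0, 0.01, 0.0, 0.01, 0.0]

    def test_two_pulse_long_interval_recovers_fully(self, no_tarp_wt):
        p = tg.make_two_pulse(0.5, 5.0, 0.02, 0.01)
        trace = tg.simulate(no_tarp_wt, p)
        on = p.pulse_onsets()
        cond = trace.current[trace.window(on[0], on[0] + 0.5)].max()
        test = trace.current[trace.window(on[1], on[1] + 0.02)].max()
        assert test / cond == pytest.approx(1.0, abs=5e-3)

    def test_train_structure_and_errors(self):
        p = tg.make_train(0.001, 200.0, 10, 0.01)
        assert len(p.pulse_onsets()) == 10
        assert np.allclose(np.diff(p.pulse_onsets()), 0.005)
        with pytest.raises(ValueError):
            tg.make_train(0.01, 200.0, 10, 0.01)  # pulse longer than period
        single = tg.make_train(0.001, 200.0, 1, 0.01)
        assert len(single.pulse_onsets()) == 1

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            pr.Segment(-1.0, 0.01)
        with pytest.raises(ValueError):
            pr.Segment(1.0, -0.01)


class TestSimulate:
    def test_occupancy_simplex_preserved(self, tarp_wt):
        trace = tg.simulate(tarp_wt, tg.make_pulse(0.1, 0.01, post=0.05))
        sums = trace.occupancy.sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-8
        assert trace.occupancy.min() >= -1e-12

    def test_stationarity_at_zero_concentration(self, tarp_wt):
        p = pr.ConcentrationProtocol((pr.Segment(0.2, 0.0),))
        trace = tg.simulate(tarp_wt, p, initial="equilibrium")
        assert np.ptp(trace.current) < 1e-12
        assert np.abs(trace.occupancy - trace.occupancy[0]).max() < 1e-9

    def test_requires_balanced_scheme(self):
        raw = tg.build_scheme("TARP")
        with pytest.raises(ValueError, match="balanced"):
            tg.simulate(raw, tg.make_pulse(0.01, 0.01))
        tg.simulate(raw, tg.make_pulse(0.01, 0.01, post=0.01),
                    require_balanced=False)  # explicit opt-out works

    def test_invalid_initial_vector(self, tarp_wt):
        with pytest.raises(ValueError):
            tg.simulate(tarp_wt, tg.make_pulse(0.01, 0.01),
                        initial=np.ones(tarp_wt.n_states))

    def test_matches_adaptive_ode_oracle(self, tarp_wt):
        protocol = tg.make_pulse(0.05, 0.01, pre=0.005, post=0.02)
        trace = tg.simulate(tarp_wt, protocol)
        p0 = tg.equilibrium_occupancy(tarp_wt, 0.0)
        qs = {c: tg.generator_matrix(tarp_wt, c) for c in (0.0, 0.01)}

        def rhs(t, p):
            c = protocol.concentration_at(np.array([t]))[0]
            return p @ qs[c]

        edges = np.concatenate([[0.0], protocol.boundaries()])
        p = p0
        sol_occ = np.empty_like(trace.occupancy)
        for k in range(len(protocol.segments)):
            mask = (trace.time >= edges[k] - 1e-12) & \
                   (trace.time < edges[k + 1] - 1e-12)
            if k == len(protocol.segments) - 1:
                mask |= trace.time >= edges[k + 1] - 1e-12
            ts = trace.time[mask]
            sol = solve_ivp(rhs, (edges[k], edges[k + 1]), p,
                            t_eval=ts, rtol=1e-10, atol=1e-12,
                            method="LSODA")
            sol_occ[mask] = sol.y.T
            p = solve_ivp(rhs, (edges[k], edges[k + 1]), p,
                          rtol=1e-10, atol=1e-12, method="LSODA").y[:, -1]
        assert np.abs(trace.occupancy - sol_occ).max() < 1e-6

    def test_time_grid_refinement_invariance(self, no_tarp_wt):
        scalars = []
        for dt in (5e-5, 2.5e-5):
            trace = tg.simulate(no_tarp_wt, tg.make_pulse(
                0.5, 0.01, post=0.02, sample_interval=dt))
            peak, steady, pct = tg.peak_and_steady(trace)
            scalars.append((peak, steady))
        (p1, s1), (p2, s2) = scalars
        assert abs(p1 / p2 - 1) < 1e-3
        assert abs(s1 / s2 - 1) < 1e-3

    def test_tarp_beats_no_tarp_peak_and_steady(self, tarp_wt, no_tarp_wt):
        protocol = tg.make_pulse(0.5, 0.01, post=0.02)
        t_tarp = tg.simulate(tarp_wt, protocol)
        t_no = tg.simulate(no_tarp_wt, protocol)
        assert t_tarp.popen.max() > t_no.popen.max()
        assert tg.peak_and_steady(t_tarp)[2] > tg.peak_and_steady(t_no)[2]


class TestStochastic:
    def test_same_seed_identical(self, no_tarp_wt):
        p = tg.make_pulse(0.01, 0.01, pre=0.002, post=0.005)
        a = tg.stochastic_simulate(no_tarp_wt, p, n_channels=50, seed=7)
        b = tg.stochastic_simulate(no_tarp_wt, p, n_channels=50, seed=7)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_single_channel_occupies_one_state(self, no_tarp_wt):
        p = tg.make_pulse(0.01, 0.01, pre=0.002, post=0.005)
        one = tg.stochastic_simulate(no_tarp_wt, p, n_channels=1, seed=3)
        assert np.all(one.occupancy.sum(axis=1) == 1)
        assert np.all(np.isin(one.occupancy, (0.0, 1.0)))

    def test_ensemble_converges_to_deterministic(self, no_tarp_wt):
        p = tg.make_pulse(0.1, 0.01, pre=0.005, post=0.02)
        n = 4000
        ens = tg.stochastic_simulate(no_tarp_wt, p, n_channels=n, seed=11)
        det = tg.simulate(no_tarp_wt, p)
        # binomial standard error per state/time, floored for p ~ 0
        se = np.sqrt(np.clip(det.occupancy * (1 - det.occupancy), 1e-6, None)
                     / n)
        z = np.abs(ens.occupancy - det.occupancy) / se
        # all samples within 3 MC standard errors except rare tails
        assert np.mean(z > 3) < 0.01
        assert np.abs(ens.current - det.current).max() < \
            6 * np.sqrt(det.current.max() / n)


class TestPeakAndSteady:
    def test_flat_trace_ratio_100(self, tarp_wt):
        p = pr.ConcentrationProtocol(
            (pr.Segment(0.01, 0.0), pr.Segment(0.2, 0.01)))
        trace = tg.simulate(tarp_wt, p)
        flat = pr.SimTrace(trace.time, trace.occupancy,
                           trace.popen, np.ones_like(trace.current),
                           trace.state_names, p)
        peak, steady, pct = tg.peak_and_steady(flat)
        assert pct == pytest.approx(100.0)

    def test_empty_window_rejected(self, tarp_wt):
        trace = tg.simulate(tarp_wt, tg.make_pulse(0.05, 0.01, post=0.01))
        with pytest.raises(ValueError):
            trace.window(0.02, 0.02)
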