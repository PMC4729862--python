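"""Scheme construction, microscopic reversibility and equilibrium."""

import numpy as np
import pytest

import tarpgate as tg
from tarpgate import scheme as sc


class TestConstruction:
    def test_no_tarp_has_six_states_one_open(self):
        s = tg.build_scheme("noTARP")
        assert s.n_states == 6
        assert s.open_states() == ("AR*",)

    def test_tarp_doubles_states_two_open_conductance_ratio(self):
        s = tg.build_scheme("TARP")
        assert s.n_states == 12
        opens = s.open_states()
        assert opens == ("ARs*", "ARS*")
        g = {st.name: st.conductance for st in s.states}
        assert g["ARS*"] / g["ARs*"] == pytest.approx(2.5)

    def test_ctz_variant_throttles_desensitization_entries(self):
        s = tg.build_scheme("TARP+CTZ")
        for name in ("d0+", "d1+", "d2*+"):
            assert s.rates[name] == pytest.approx(0.1)
        # d2+ untouched unless explicitly requested
        assert s.rates["d2+"] == pytest.approx(120.0)
        s2 = tg.build_scheme("TARP+CTZ", ctz_block_deep_basal=True)
        assert s2.rates["d2+"] == pytest.approx(0.1)

    def test_kainate_overrides_and_conductance(self):
        s = tg.build_scheme("kainate")
        assert s.rates["beta"] == 1_600.0
        assert s.rates["alpha"] == 30_000.0
        assert s.rates["beta_s"] == 100_000.0
        g = {st.name: st.conductance for st in s.states}
        assert g["ARs*"] == pytest.approx(0.08)
        assert g["ARS*"] == pytest.approx(1.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            tg.build_scheme("TARP++")

    def test_rate_set_validation(self):
        with pytest.raises(KeyError):
            tg.RateSet(nonsense=1.0)
        with pytest.raises(ValueError):
            tg.RateSet(**{"beta": -5.0})

    def test_state_graph_connected(self):
        for variant in tg.VARIANTS:
            tg.build_scheme(variant).validate()


class TestMutantTrials:
    def test_table_values(self):
        s = tg.apply_mutant_trial(tg.build_scheme("TARP"), 7)
        assert s.rates["d2-"] == pytest.approx(19.9)
        assert s.rates["d2*-"] == pytest.approx(5.26)
        s0 = tg.apply_mutant_trial(tg.build_scheme("TARP"), 0)
        assert s0.rates["d2-"] == pytest.approx(0.16)
        assert s0.rates["d2*-"] == pytest.approx(0.18)

    def test_idempotent(self):
        s1 = tg.apply_mutant_trial(tg.build_scheme("TARP"), 7)
        s2 = tg.apply_mutant_trial(s1, 7)
        assert s1.rates == s2.rates
        assert s1.transitions == s2.transitions

    def test_bad_trial_id(self):
        with pytest.raises(ValueError):
            tg.apply_mutant_trial(tg.build_scheme("TARP"), 9)

    def test_trial_restricted_to_main_variants(self):
        with pytest.raises(ValueError):
            tg.apply_mutant_trial(tg.build_scheme("kainate"), 7)

    def test_clears_balanced_flag(self):
        balanced = tg.balanced_scheme("TARP")
        assert balanced.balanced
        assert not tg.apply_mutant_trial(balanced, 3).balanced

    def test_shutting_rate_compensation_spans_series(self):
        # Fast-recovering mutants shut faster; the wild-type proxy maps
        # back to a ~1,000 /s deactivation anchor.
        alphas = [sc.mutant_alpha(sc.MUTANT_TRIALS[t][0]) for t in range(9)]
        assert all(a < b for a, b in zip(alphas, alphas[1:]))
        burst = (40_000 + 8_000 + 300) / 40_000
        assert alphas[7] == pytest.approx(1000 * burst)


class TestReversibility:
    def test_unbalanced_open_square_ratio(self):
        s = tg.build_scheme("TARP")
        square = next(r for c, r in tg.cycle_imbalance(s)
                      if set(c) == {"ARs", "ARs*", "ARS*", "ARS"})
        # orientation of the reported cycle is arbitrary
        assert max(square, 1 / square) == pytest.approx(120_000 / 105_000,
                                                        rel=1e-12)

    def test_balanced_s_star_plus(self, tarp_default):
        # Closed-form cycle balance: s*+ = s+ * beta_s * s*- / (beta * s-)
        assert tarp_default.rates["s*+"] == pytest.approx(13.125, rel=1e-12)

    def test_all_cycles_balanced_after_enforcement(self):
        for variant in tg.VARIANTS:
            for trial in (None, 7) if variant in ("noTARP", "TARP") else (None,):
                b, _ = tg.enforce_microscopic_reversibility(
                    tg.build_scheme(variant, trial=trial))
                worst = max(abs(r - 1) for _, r in tg.cycle_imbalance(b))
                assert worst <= 1e-10

    def test_report_lists_adjusted_rates(self):
        _, report = tg.enforce_microscopic_reversibility(
            tg.build_scheme("TARP"))
        names = {name for name, _, _ in report}
        assert "s*+" in names and "kd-" in names

    def test_balancing_error_when_no_dependent_rate(self):
        with pytest.raises(ValueError, match="unbalanced|span"):
            tg.enforce_microscopic_reversibility(
                tg.build_scheme("TARP"), dependent_rates=["kd-"])

    def test_wild_type_trial_keeps_printed_open_cycle_balance(self):
        # alpha(WT) cancels against the fixed superactive shutting, so the
        # balanced TARP activation rate equals the default-scheme value.
        b = tg.balanced_scheme("TARP", 7)
        assert b.rates["s*+"] == pytest.approx(13.125, rel=1e-9)


class TestGeneratorAndEquilibrium:
    @pytest.mark.parametrize("conc", [0.0, 1e-6, 0.01, 1.0])
    def test_rows_sum_to_zero(self, tarp_wt, conc):
        q = tg.generator_matrix(tarp_wt, conc)
        scale = max(np.abs(q).max(), 1.0)
        assert np.abs(q.sum(axis=1)).max() < 1e-12 * scale

    def test_zero_concentration_kills_binding(self, no_tarp_wt):
        q = tg.generator_matrix(no_tarp_wt, 0.0)
        i, j = no_tarp_wt.state_index("R"), no_tarp_wt.state_index("AR")
        assert q[i, j] == 0.0

    def test_binding_entry_scales_with_concentration(self):
        s = tg.build_scheme("noTARP")
        q = tg.generator_matrix(s, 0.01)
        i, j = s.state_index("R"), s.state_index("AR")
        assert q[i, j] == pytest.approx(5_000_000 * 0.01)

    def test_negative_concentration_rejected(self, no_tarp_wt):
        with pytest.raises(ValueError):
            tg.generator_matrix(no_tarp_wt, -1e-3)

    def test_equilibrium_is_probability_vector(self, tarp_wt):
        pi = tg.equilibrium_occupancy(tarp_wt, 0.01)
        assert pi.min() >= 0
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_conc_equilibrium_confined_to_unbound(self, no_tarp_wt):
        pi = tg.equilibrium_occupancy(no_tarp_wt, 0.0)
        bound = [i for i, name in enumerate(no_tarp_wt.state_names)
                 if name.startswith("A")]
        assert np.abs(pi[bound]).max() < 1e-12
        assert pi[no_tarp_wt.state_index("R")] == pytest.approx(1.0)

    def test_detailed_balance_fluxes(self, tarp_wt):
        # Balanced scheme: per-edge probability fluxes cancel pairwise.
        conc = 0.003
        pi = tg.equilibrium_occupancy(tarp_wt, conc)
        idx = {n: i for i, n in enumerate(tarp_wt.state_names)}
        for t in tarp_wt.transitions:
            f, b = t.rates(tarp_wt.rates)
            if t.ligand:
                f *= conc
            fwd = pi[idx[t.source]] * f
            bwd = pi[idx[t.target]] * b
            assert fwd == pytest.approx(bwd, rel=1e-6, abs=1e-14)

    def test_long_time_propagation_oracle(self, tarp_wt):
        # Independent stationary-distribution oracle: propagate an
        # arbitrary start vector far past the slowest relaxation time.
        import scipy.linalg
        q = tg.generator_matrix(tarp_wt, 0.01)
        v = np.full(q.shape[0], 1.0 / q.shape[0])
        kernel = scipy.linalg.expm(q.T * 500.0)
        v1 = kernel @ v
        v1 /= v1.sum()
        v2 = kernel @ v1  # doubling the horizon must change nothing
        v2 /= v2.sum()
        assert np.abs(v2 - v1).max() < 1e-8
        pi = tg.equilibrium_occupancy(tarp_wt, 0.01)
        assert np.abs(pi - v1).max() < 1e-8

    def test_equilibrium_open_probability_monotone_in_trial(self):
        po = []
        for trial in range(9):
            s = tg.balanced_scheme("TARP", trial)
            pi = tg.equilibrium_occupancy(s, 0.01)
            po.append(sum(pi[s.state_index(o)] for o in s.open_states()))
        assert all(a < b for a, b in zip(po, po[1:]))

    def test_basal_superactive_fraction_independent_of_trial(self):
        # The resting-state TARP equilibrium is set only by s+/s-.
        for trial in (0, 7, 8):
            s = tg.balanced_scheme("TARP", trial)
            frac = tg.basal_superactive_fraction(s)
            assert frac == pytest.approx(0.07 / 1.07, rel=1e-9)
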