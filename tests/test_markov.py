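"""Markov engine: conversions, matrices, cohort propagation, discounting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statin_cua.markov import (DiscountSpec, HealthState, N_STATES,
                               STATE_INDEX, ValidationError,
                               annualize_probability, band_for_age,
                               build_transition_matrix, compound_probability,
                               discounted_totals, lifetime_ascvd_fraction,
                               run_cohort)
from statin_cua.strategy import TreatmentEffects

from conftest import make_uniform_table

I_DF = STATE_INDEX[HealthState.DISEASE_FREE_UNTREATED]
I_STATIN = STATE_INDEX[HealthState.DISEASE_FREE_ON_STATIN]
I_IHD = STATE_INDEX[HealthState.NONFATAL_OTHER_IHD]
I_FATAL = STATE_INDEX[HealthState.FATAL_ASCVD]
I_DEATH = STATE_INDEX[HealthState.FATAL_NON_ASCVD]


class TestProbabilityConversion:
    @pytest.mark.parametrize("p10, expected", [
        (0.0, 0.0),
        (0.10, 0.0104807),
    ])
    def test_annualize_closed_form(self, p10, expected):
        assert annualize_probability(p10) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("bad", [1.0, -0.1, 1.5])
    def test_annualize_domain_errors(self, bad):
        with pytest.raises(ValueError):
            annualize_probability(bad)

    def test_compound_identities(self):
        assert compound_probability(0.0104807, 10) == pytest.approx(0.10,
                                                                    abs=1e-6)
        assert compound_probability(0.37, 1) == pytest.approx(0.37)
        assert compound_probability(0.0, 25) == 0.0
        with pytest.raises(ValueError):
            compound_probability(0.1, -1)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_round_trip(self, p):
        assert compound_probability(annualize_probability(p), 10) == \
            pytest.approx(p, abs=1e-9)


class TestBandMapping:
    def test_bands_and_carry_forward(self):
        assert band_for_age(30) == "30-34"
        assert band_for_age(69.9) == "65-69"
        assert band_for_age(74) == "70-75"
        assert band_for_age(92) == "70-75"
        with pytest.raises(ValueError):
            band_for_age(25)


class TestTransitionMatrix:
    def test_zero_hazards_give_identity(self):
        table = make_uniform_table(0, 0, 0, 0, 0, post_fatal=0, post_cross=0,
                                   post_death=0)
        m = build_transition_matrix(table, "female", "50-54", "overall")
        # myopathy recovery is structural, every other state stays put
        expected = np.eye(N_STATES)
        i_myo = STATE_INDEX[HealthState.ADVERSE_MYOPATHY_RECOVERED]
        expected[i_myo, i_myo] = 0.0
        expected[i_myo, I_DF] = 1.0
        np.testing.assert_allclose(m, expected)

    def test_rows_are_stochastic_and_absorbing(self, uniform_table):
        m = build_transition_matrix(uniform_table, "male", "60-64", "overall")
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m[I_FATAL, I_FATAL] == 1.0
        assert m[I_DEATH, I_DEATH] == 1.0

    def test_relative_risk_moves_mass_to_stay(self):
        table = make_uniform_table(0.0, 0.0100, 0.0, 0.0, 0.0, post_fatal=0,
                                   post_cross=0, post_death=0)
        effects = TreatmentEffects(rr_nonfatal_ihd=0.67, rr_nonfatal_is=1.0,
                                   rr_fatal_ascvd=1.0, p_adverse_diabetes=0,
                                   p_adverse_myopathy=0,
                                   p_discontinue_other=0)
        m = build_transition_matrix(table, "female", "40-44", "overall",
                                    treatment=effects)
        assert m[I_STATIN, I_IHD] == pytest.approx(0.0067)
        assert m[I_STATIN, I_STATIN] == pytest.approx(
            m[I_DF, I_DF] + 0.0033)

    def test_overfull_table_rejected_naming_stratum(self):
        with pytest.raises(ValidationError, match="30-34"):
            make_uniform_table(0.5, 0.5, 0.3, 0.0, 0.0)

    def test_overfull_treated_row_raises_with_stratum(self):
        table = make_uniform_table(0.3, 0.3, 0.3, 0.05, 0.05)
        effects = TreatmentEffects(rr_nonfatal_ihd=1.0, rr_nonfatal_is=1.0,
                                   rr_fatal_ascvd=1.0,
                                   p_adverse_diabetes=0.3,
                                   p_adverse_myopathy=0.3,
                                   p_discontinue_other=0.0)
        with pytest.raises(ValidationError, match="50-54"):
            build_transition_matrix(table, "female", "50-54", "overall",
                                    treatment=effects)


def _constant_matrix(p_death_annual: float) -> np.ndarray:
    m = np.eye(N_STATES)
    m[I_DF, I_DF] = 1.0 - p_death_annual
    m[I_DF, I_DEATH] = p_death_annual
    return m


def _init(state_index: int) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[state_index] = 1.0
    return v


class TestRunCohort:
    def test_identity_matrices_keep_occupancy(self):
        trace = run_cohort([np.eye(N_STATES)] * 5, _init(I_DF), 5)
        np.testing.assert_allclose(
            trace.occupancy,
            np.broadcast_to(trace.occupancy[0], trace.occupancy.shape))
        trace.validate()

    def test_absorbing_state_traps_mass(self, uniform_table):
        m = build_transition_matrix(uniform_table, "male", "50-54", "overall")
        trace = run_cohort([m] * 20, _init(I_FATAL), 20)
        assert trace.occupancy[:, I_FATAL].min() == 1.0

    def test_survival_matches_closed_form(self):
        trace = run_cohort([_constant_matrix(0.1)] * 10, _init(I_DF), 10)
        assert trace.occupancy[10, I_DF] == pytest.approx(0.9 ** 10,
                                                          abs=1e-12)

    def test_horizon_must_be_positive(self):
        with pytest.raises(ValueError):
            run_cohort([np.eye(N_STATES)], _init(I_DF), 0)

    def test_matches_path_enumeration_oracle(self, uniform_table):
        """Expected-value propagation equals the probability-weighted sum
        over all explicit state paths (brute force, 5 cycles)."""
        m = build_transition_matrix(uniform_table, "female", "60-64",
                                    "overall")
        cycles = 5
        trace = run_cohort([m] * cycles, _init(I_DF), cycles)
        support = [j for j in range(N_STATES)
                   if m[:, j].max() > 0 or j == I_DF]
        occupancy = np.zeros(N_STATES)
        for path in itertools.product(support, repeat=cycles):
            p, state = 1.0, I_DF
            for nxt in path:
                p *= m[state, nxt]
                if p == 0.0:
                    break
                state = nxt
            occupancy[path[-1]] += p
        np.testing.assert_allclose(trace.occupancy[cycles], occupancy,
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conservation_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        mats = []
        for _ in range(15):
            m = rng.dirichlet(np.ones(N_STATES), size=N_STATES)
            for s in (I_FATAL, I_DEATH):
                m[s] = 0.0
                m[s, s] = 1.0
            mats.append(m)
        init = rng.dirichlet(np.ones(N_STATES))
        trace = run_cohort(mats, init, 15)
        trace.validate()
        for col in (I_FATAL, I_DEATH):
            assert np.all(np.diff(trace.occupancy[:, col]) >= -1e-12)


class TestDiscountedTotals:
    def _flat_cost_trace(self, cycles):
        trace = run_cohort([np.eye(N_STATES)] * (cycles - 1), _init(I_DF),
                           cycles - 1)
        cost = np.zeros(N_STATES)
        cost[I_DF] = 100.0
        return trace, cost

    def test_zero_rate_is_plain_sum(self):
        trace, cost = self._flat_cost_trace(3)
        pv_cost, _ = discounted_totals(trace, cost, np.zeros(N_STATES),
                                       DiscountSpec(0.0))
        assert pv_cost == pytest.approx(300.0)

    def test_five_percent_three_cycles(self):
        trace, cost = self._flat_cost_trace(3)
        pv_cost, pv_q = discounted_totals(trace, cost, np.zeros(N_STATES),
                                          DiscountSpec(0.05))
        assert pv_cost == pytest.approx(100 + 100 / 1.05 + 100 / 1.05 ** 2,
                                        abs=1e-9)
        assert pv_cost == pytest.approx(285.94, abs=0.01)
        assert pv_q == 0.0

    def test_pv_non_increasing_in_rate(self):
        trace, cost = self._flat_cost_trace(30)
        pvs = [discounted_totals(trace, cost, np.zeros(N_STATES),
                                 DiscountSpec(r))[0]
               for r in (0.0, 0.02, 0.05, 0.08, 0.2)]
        assert all(a >= b for a, b in zip(pvs, pvs[1:]))


class TestLifetimeFraction:
    def test_zero_hazard_gives_zero(self):
        trace = run_cohort([np.eye(N_STATES)] * 10, _init(I_DF), 10)
        assert lifetime_ascvd_fraction(trace) == 0.0

    def test_certain_fatal_event_gives_one(self):
        m = np.eye(N_STATES)
        m[I_DF, I_DF] = 0.0
        m[I_DF, I_FATAL] = 1.0
        trace = run_cohort([m] * 3, _init(I_DF), 3)
        assert lifetime_ascvd_fraction(trace) == pytest.approx(1.0)

    def test_constant_hazard_closed_form(self):
        m = np.eye(N_STATES)
        m[I_DF, I_DF] = 0.98
        m[I_DF, STATE_INDEX[HealthState.NONFATAL_IS]] = 0.02
        m[STATE_INDEX[HealthState.NONFATAL_IS],
          STATE_INDEX[HealthState.NONFATAL_IS]] = 1.0
        trace = run_cohort([m] * 40, _init(I_DF), 40)
        assert lifetime_ascvd_fraction(trace) == pytest.approx(
            1 - 0.98 ** 40, abs=1e-12)
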