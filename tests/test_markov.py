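"""Cohort engine: discounting, QALY arithmetic, propagation, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glaucoma_cea import (
    HealthState,
    StateRewards,
    TransitionModel,
    ValidationError,
    discount_factor,
    qaly,
    random_scenario,
    run_cohort,
)
from glaucoma_cea.markov import N_STATES

from _oracle import binomial_3se_band, microsim_occupancy


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [
            (0.03, 0, 1.0),
            (0.0, 17, 1.0),
            (0.03, 1, 1.0 / 1.03),
            (0.05, 10, 1.05**-10),
        ],
    )
    def test_values(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("rate, cycle", [(-0.01, 1), (0.03, -1), (0.03, 1.5)])
    def test_domain_errors(self, rate, cycle):
        with pytest.raises(ValidationError):
            discount_factor(rate, cycle)


class TestQaly:
    @pytest.mark.parametrize(
        "utility, years, expected",
        [(0.5, 1, 0.5), (1.0, 7, 7.0), (0.87, 2, 1.74), (0.0, 3, 0.0)],
    )
    def test_values(self, utility, years, expected):
        assert qaly(utility, years) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("utility, years", [(1.2, 1), (-0.1, 1), (0.5, -2)])
    def test_domain_errors(self, utility, years):
        with pytest.raises(ValidationError):
            qaly(utility, years)


class TestTransitionModel:
    def test_rejects_non_stochastic_rows(self):
        m = np.eye(N_STATES)
        m[0, 0] = 0.9
        with pytest.raises(ValidationError, match="sum to 1"):
            TransitionModel(m)

    def test_rejects_recovery_moves(self):
        m = np.eye(N_STATES)
        m[2, 1] = 0.1
        m[2, 2] = 0.9
        with pytest.raises(ValidationError, match="recovery"):
            TransitionModel(m)

    def test_rejects_non_absorbing_blindness(self):
        probs = [0.1, 0.1, 0.1, 0.1]
        m = TransitionModel.from_progression(probs).matrix.copy()
        m[4, 4] = 0.0
        m[4, 3] = 0.0
        m[4] = 0.0
        m[4, 4] = 0.9
        m[4, 3] = 0.1
        with pytest.raises(ValidationError):
            TransitionModel(m)

    def test_progression_roundtrip(self):
        probs = np.array([0.3, 0.2, 0.1, 0.4])
        tm = TransitionModel.from_progression(probs, "treated")
        assert np.allclose(tm.progression_probs, probs)
        assert tm.matrix.sum(axis=1) == pytest.approx(np.ones(N_STATES))


class TestRunCohort:
    def test_identity_matrix_accrues_constant_reward(self):
        """A motionless all-mild cohort accrues utility every accrual point."""
        tm = TransitionModel(np.eye(N_STATES))
        rewards = StateRewards([1.0, 0.87, 0.8, 0.7, 0.5], np.zeros(N_STATES))
        trace = run_cohort([0, 1, 0, 0, 0], tm, rewards, n_cycles=30, discount_rate=0.0)
        assert trace.discounted_qaly_cum == pytest.approx(31 * 0.87, rel=1e-12)

    def test_two_state_chain_matches_closed_form(self):
        """SEVERE -> BLIND with per-cycle probability p: absorbing occupancy
        follows 1 - (1-p)^t exactly."""
        p = 0.23
        tm = TransitionModel.from_progression([0, 0, 0, p])
        rewards = StateRewards(np.linspace(1, 0.5, 5), np.zeros(N_STATES))
        trace = run_cohort([0, 0, 0, 1, 0], tm, rewards, 30, 0.0)
        t = np.arange(31)
        assert np.allclose(trace.occupancy[:, 4], 1 - (1 - p) ** t, atol=1e-12)

    def test_two_state_chain_matches_microsimulation(self, rng):
        """Cohort result agrees with a 1e5-individual microsimulation."""
        p = 0.23
        tm = TransitionModel.from_progression([0, 0, 0, p])
        init = np.array([0.0, 0, 0, 1.0, 0])
        n = 100_000
        freq = microsim_occupancy(tm.matrix, init, 30, n, rng)
        expected = 1 - (1 - p) ** np.arange(31)
        assert np.all(np.abs(freq[:, 4] - expected) <= binomial_3se_band(expected, n))

    def test_validation_rejects_bad_inputs(self):
        tm = TransitionModel(np.eye(N_STATES))
        rewards = StateRewards(np.linspace(1, 0.5, 5), np.zeros(N_STATES))
        with pytest.raises(ValidationError):
            run_cohort([0.5, 0.5, 0.5, 0, 0], tm, rewards, 10, 0.0)
        with pytest.raises(ValidationError):
            run_cohort([1, 0, 0, 0, 0], tm, rewards, 0, 0.0)
        with pytest.raises(ValidationError):
            run_cohort([1, 0, 0, 0, 0], tm, rewards, 10, 0.0, reward_timing="middle")

    def test_end_of_cycle_timing_drops_entry_accrual(self):
        tm = TransitionModel(np.eye(N_STATES))
        rewards = StateRewards([1.0, 0.9, 0.8, 0.7, 0.5], np.full(N_STATES, 10.0))
        start = run_cohort([1, 0, 0, 0, 0], tm, rewards, 10, 0.0, "start")
        end = run_cohort([1, 0, 0, 0, 0], tm, rewards, 10, 0.0, "end")
        assert start.discounted_qaly_cum == pytest.approx(end.discounted_qaly_cum + 1.0)
        assert start.discounted_cost_cum == pytest.approx(end.discounted_cost_cum + 10.0)

    def test_trace_csv_layout(self, tmp_path):
        tm = TransitionModel.from_progression([0.2, 0.2, 0.2, 0.2])
        rewards = StateRewards(np.linspace(1, 0.5, 5), np.linspace(10, 200, 5))
        trace = run_cohort([1, 0, 0, 0, 0], tm, rewards, 5, 0.03)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == (
            "cycle,at_risk,mild,moderate,severe,blind,"
            "cycle_cost,cycle_qaly,cum_disc_cost,cum_disc_qaly"
        )


class TestEngineInvariants:
    """Structural properties over randomly generated scenarios."""

    @pytest.mark.parametrize("seed", range(100))
    def test_row_sums_blind_monotonicity_and_dominance(self, seed):
        """Occupancy rows stay stochastic, blindness never recedes, and the
        cohort's cumulative severity distribution only worsens with time."""
        cfg = random_scenario(seed)
        strat = cfg.strategies[cfg.reference_strategy]
        trace = run_cohort(
            [1, 0, 0, 0, 0],
            strat.untreated_transitions,
            cfg.rewards,
            cfg.horizon,
            cfg.discount_rate,
        )
        occ = trace.occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        blind = occ[:, HealthState.BLIND]
        assert np.all(np.diff(blind) >= -1e-12)
        cum = occ.cumsum(axis=1)  # P(state <= k) per cycle
        assert np.all(np.diff(cum, axis=0) <= 1e-12)

    @pytest.mark.parametrize("seed", [11, 42, 1234])
    def test_cohort_matches_microsimulation_oracle(self, seed):
        """Deterministic cohort propagation equals an independent
        per-individual Monte Carlo within 3 binomial standard errors."""
        cfg = random_scenario(seed)
        strat = cfg.strategies[cfg.reference_strategy]
        tm = strat.treated_transitions
        init = np.array([1.0, 0, 0, 0, 0])
        n_cycles = min(cfg.horizon, 20)
        trace = run_cohort(init, tm, cfg.rewards, n_cycles, 0.0)
        n = 100_000
        freq = microsim_occupancy(
            tm.matrix, init, n_cycles, n, np.random.default_rng(seed + 1)
        )
        band = binomial_3se_band(trace.occupancy, n)
        assert np.all(np.abs(freq - trace.occupancy) <= band)

    @given(rate_pair=st.tuples(st.floats(0, 0.2), st.floats(0, 0.2)), seed=st.integers(0, 50))
    def test_discounting_monotone_in_rate(self, rate_pair, seed):
        """Cumulative discounted reward never increases with the rate."""
        lo, hi = sorted(rate_pair)
        cfg = random_scenario(seed)
        strat = cfg.strategies[cfg.reference_strategy]
        q = [
            run_cohort(
                [1, 0, 0, 0, 0], strat.treated_transitions, cfg.rewards, 15, r
            ).discounted_qaly_cum
            for r in (lo, hi)
        ]
        assert q[1] <= q[0] + 1e-9
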