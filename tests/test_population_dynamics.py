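"""Imitation dynamics: payoffs, single steps, and the rejection-free process.

Oracles: exhaustive enumeration over ordered individual pairs for payoffs
and jump laws, and exact birth-death absorption solves for fixation
fractions.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stgames import (
    Game,
    ImitationRule,
    PopulationState,
    StabilityConfig,
    imitation_probability,
    individual_payoff,
    run_until_stable,
    step_accelerated,
    step_direct,
)
from stgames.game_space import index_of_code


def enumeration_jump_law(counts, W, dpmax):
    """Oracle: P(i replaced by j | change) by enumerating ordered pairs of
    individuals, each drawn with probability 1/(N(N-1))."""
    idx = np.repeat(np.arange(counts.size), counts)
    N = idx.size
    joint = np.zeros((counts.size, counts.size))
    for f in range(N):
        for o in range(N):
            if f == o:
                continue
            i, j = idx[f], idx[o]
            if i == j:
                continue
            pf = (W[i] @ counts - W[i, i]) / (N - 1)
            po = (W[j] @ counts - W[j, j]) / (N - 1)
            p = min(1.0, max(0.0, 0.5 * (1 + (po - pf) / dpmax)))
            joint[i, j] += p / (N * (N - 1))
    return joint / joint.sum()


class TestIndividualPayoff:
    def test_homogeneous_population(self, pd_rule):
        state = PopulationState(np.array([0] * 5 + [10] + [0] * 10))
        assert individual_payoff(state, 5, pd_rule.W) == pytest.approx(pd_rule.W[5, 5])

    def test_two_individuals(self, pd_rule):
        counts = np.zeros(16, dtype=int)
        counts[3], counts[7] = 1, 1
        state = PopulationState(counts)
        assert individual_payoff(state, 3, pd_rule.W) == pytest.approx(pd_rule.W[3, 7])

    def test_absent_strategy_rejected(self, pd_rule):
        state = PopulationState(np.array([2] + [0] * 15))
        with pytest.raises(ValueError):
            individual_payoff(state, 1, pd_rule.W)

    def test_matches_exhaustive_average(self, pd_rule, rng):
        counts = np.zeros(16, dtype=int)
        counts[[1, 6, 11]] = [4, 3, 5]
        state = PopulationState(counts)
        N = state.N
        idx = np.repeat(np.arange(16), counts)
        for i in (1, 6, 11):
            # Average payoff of one i-individual over its N-1 possible opponents.
            opponents = list(idx)
            opponents.remove(i)
            oracle = np.mean([pd_rule.W[i, j] for j in opponents])
            assert individual_payoff(state, i, pd_rule.W) == pytest.approx(oracle)


class TestImitationProbability:
    def test_drift_at_zero(self):
        assert imitation_probability(0.0, 2.0) == 0.5

    def test_extremes(self):
        assert imitation_probability(2.0, 2.0) == 1.0
        assert imitation_probability(-2.0, 2.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            imitation_probability(2.5, 2.0)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_complementary(self, a, b):
        pa = imitation_probability(a, 1.0)
        pb = imitation_probability(b, 1.0)
        if a < b:
            assert pa <= pb
        assert imitation_probability(a, 1.0) + imitation_probability(-a, 1.0) == pytest.approx(1.0)


class TestSteps:
    def test_direct_homogeneous_unchanged(self, pd_rule, rng):
        state = PopulationState(np.array([0] * 9 + [50] + [0] * 6))
        out = step_direct(state, pd_rule, rng)
        np.testing.assert_array_equal(out.counts, state.counts)

    def test_direct_conserves_population(self, pd_rule, rng):
        counts = np.zeros(16, dtype=int)
        counts[[0, 9, 15]] = [10, 20, 5]
        state = PopulationState(counts)
        for _ in range(200):
            state = step_direct(state, pd_rule, rng)
            assert state.N == 35

    def test_accelerated_rejects_homogeneous(self, pd_rule, rng):
        state = PopulationState(np.array([50] + [0] * 15))
        with pytest.raises(ValueError):
            step_accelerated(state, pd_rule, rng)

    def test_accelerated_waiting_time_closed_form(self, pd_rule, rng):
        counts = np.zeros(16, dtype=int)
        counts[[2, 9]] = [30, 20]
        state = PopulationState(counts)
        N = 50
        _, waiting = step_accelerated(state, pd_rule, rng)
        expected = 2 * N * (N - 1) / (N**2 - np.sum(counts.astype(float) ** 2))
        assert waiting == pytest.approx(expected)

    def test_neutral_jump_law_proportional_to_products(self, rng):
        """With equal payoffs the jump law i->j is proportional to n_i n_j."""
        rule = ImitationRule(W=np.full((16, 16), 0.3), delta_pi_max=1.0)
        counts = np.zeros(16, dtype=int)
        counts[[0, 4, 7]] = [6, 3, 9]
        state = PopulationState(counts)
        draws = np.zeros((16, 16))
        for _ in range(4000):
            new, _ = step_accelerated(state, rule, rng)
            diff = new.counts - state.counts
            i = int(np.flatnonzero(diff == -1)[0])
            j = int(np.flatnonzero(diff == 1)[0])
            draws[i, j] += 1
        freq = draws / draws.sum()
        prods = np.outer(counts, counts).astype(float)
        np.fill_diagonal(prods, 0)
        expected = prods / prods.sum()
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert np.all(np.abs(freq - expected) < 3.5 * se + 1e-3)

    def test_accelerated_jump_law_matches_enumeration(self, pd_rule, rng):
        """Three-strategy conditional jump law vs the ordered-pair oracle."""
        counts = np.zeros(16, dtype=int)
        counts[[0, 9, 15]] = [10, 25, 15]
        state = PopulationState(counts)
        oracle = enumeration_jump_law(counts, pd_rule.W, pd_rule.delta_pi_max)
        draws = np.zeros((16, 16))
        n_draws = 6000
        for _ in range(n_draws):
            new, _ = step_accelerated(state, pd_rule, rng)
            diff = new.counts - state.counts
            i = int(np.flatnonzero(diff == -1)[0])
            j = int(np.flatnonzero(diff == 1)[0])
            draws[i, j] += 1
        freq = draws / n_draws
        se = np.sqrt(oracle * (1 - oracle) / n_draws)
        assert np.all(np.abs(freq - oracle) < 3.5 * se + 2e-3)

    def test_direct_conditional_jumps_match_accelerated_law(self, pd_rule, rng):
        """Direct steps, conditioned on a change, follow the same law the
        accelerated process samples from."""
        counts = np.zeros(16, dtype=int)
        counts[[0, 9, 15]] = [20, 15, 15]
        state = PopulationState(counts)
        oracle = enumeration_jump_law(counts, pd_rule.W, pd_rule.delta_pi_max)
        draws = np.zeros((16, 16))
        changes = 0
        for _ in range(12000):
            new = step_direct(state, pd_rule, rng)
            diff = new.counts - state.counts
            if np.any(diff):
                i = int(np.flatnonzero(diff == -1)[0])
                j = int(np.flatnonzero(diff == 1)[0])
                draws[i, j] += 1
                changes += 1
        freq = draws / changes
        se = np.sqrt(oracle * (1 - oracle) / changes)
        assert np.all(np.abs(freq - oracle) < 3.5 * se + 5e-3)


class TestRunUntilStable:
    def test_homogeneous_start_absorbs_immediately(self, pd_rule):
        counts = np.zeros(16, dtype=int)
        counts[9] = 100
        summary = run_until_stable(PopulationState(counts), pd_rule, 1)
        assert summary.absorbed
        assert summary.elapsed_time == 0.0
        np.testing.assert_array_equal(summary.average_counts, counts)

    def test_average_counts_sum_to_population(self, harmony_rule):
        counts = np.zeros(16, dtype=int)
        counts[0], counts[15] = 190, 10
        summary = run_until_stable(PopulationState(counts), harmony_rule, 3)
        assert summary.average_counts.sum() == pytest.approx(200.0)

    def test_harmony_allc_invasion_fixes_at_exact_rate(self, harmony_game, harmony_rule):
        """AllC invading AllD in Harmony: empirical fixation fraction over
        200 runs vs the exact absorption probability of the two-strategy
        birth-death chain started at 10 mutants."""
        from stgames import birth_death_rates

        N = 200
        rates = birth_death_rates(0, 15, harmony_game, N, 0.01, rule=harmony_rule)
        # Oracle: absorption at N starting from k = 10, full linear solve.
        n = N - 1
        A = np.zeros((n, n))
        rhs = np.zeros(n)
        for k in range(n):
            A[k, k] = rates.b[k] + rates.d[k]
            if k + 1 < n:
                A[k, k + 1] = -rates.b[k]
            else:
                rhs[k] += rates.b[k]
            if k - 1 >= 0:
                A[k, k - 1] = -rates.d[k]
        u = np.linalg.solve(A, rhs)
        p_exact = u[9]  # start at 10 mutants
        counts = np.zeros(16, dtype=int)
        counts[0], counts[15] = 190, 10
        state = PopulationState(counts)
        runs = 200
        wins = 0
        for r in range(runs):
            s = run_until_stable(state, harmony_rule, 37000 + r)
            assert s.absorbed
            wins += s.final_state.counts[15] == N
        se = np.sqrt(p_exact * (1 - p_exact) / runs)
        assert abs(wins / runs - p_exact) < 3 * se + 0.01

    def test_snowdrift_anticoordination_reports_mixed(self):
        """A 0100/0101 pair at high S settles into a mixed quasi-stationary
        composition instead of absorbing."""
        from stgames import payoff_matrix

        g = Game(S=2.0, T=3.0)
        rule = ImitationRule.from_payoff_matrix(payoff_matrix(g, 0.01))
        counts = np.zeros(16, dtype=int)
        counts[index_of_code("0100")] = 190
        counts[index_of_code("0101")] = 10
        summary = run_until_stable(
            PopulationState(counts), rule, 11, StabilityConfig(event_budget=400_000)
        )
        assert not summary.absorbed and not summary.inconclusive
        fracs = summary.average_counts / 200
        assert fracs[index_of_code("0100")] > 0.05
        assert fracs[index_of_code("0101")] > 0.05
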