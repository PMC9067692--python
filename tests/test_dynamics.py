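"""Stages 3–5: imitation, group conflict, mutation; whole-period step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pggsim import (
    ParamSet,
    StageRNGs,
    Strategy,
    group_conflict_step,
    imitation_step,
    init_population,
    mutation_step,
    run_simulation,
    step,
)
from pggsim.payoffs import class_counts
from pggsim.state import check_state


def uniform_payoffs(N, value=1.0):
    return np.full((N, 6), value)


def make_cls(counts):
    z = np.zeros(counts.shape[0], dtype=np.int64)
    return class_counts(counts, z, z)


class TestImitation:
    def test_homogeneous_population_unchanged(self, rng):
        counts = np.array([[0, 10, 0, 0], [0, 10, 0, 0]])
        out = imitation_step(counts, uniform_payoffs(2), make_cls(counts), 0.0, rng)
        assert (out == counts).all()

    def test_equal_payoffs_adopt_half_the_time(self, rng):
        # two-member group, model payoff equals own -> adoption prob 0.5
        counts = np.array([[1, 1, 0, 0], [2, 0, 0, 0]])
        switches = 0
        trials = 4000
        for _ in range(trials):
            out = imitation_step(counts, uniform_payoffs(2), make_cls(counts), 0.0, rng)
            # defector in group 0 met the contributor (and vice versa)
            switches += int(out[0, Strategy.CONTRIBUTOR] == 2)
        # P(defector adopts) = 0.5; binomial s.e. ~ 0.008
        assert switches / trials == pytest.approx(0.25, abs=0.03)

    def test_triple_payoff_adopted_three_quarters(self, rng):
        # w_model = 3 * w_self -> adoption probability 3/(3+1)
        counts = np.array([[1, 1, 0, 0], [2, 0, 0, 0]])
        payoffs = np.array([[1.0, 3.0, 1.0, 1.0, 1.0, 1.0], [1.0] * 6])
        adopted = 0
        trials = 4000
        for _ in range(trials):
            out = imitation_step(counts, payoffs, make_cls(counts), 0.0, rng)
            adopted += int(out[0, Strategy.DEFECTOR] == 0)
        # defector adopts w.p. 0.75 AND contributor keeps w.p. 0.75
        assert adopted / trials == pytest.approx(0.75 * 0.75, abs=0.03)

    def test_neutral_drift_is_a_martingale(self, rng):
        # equal payoffs everywhere: expected frequency change is zero
        counts = np.array([[3, 3, 2, 2], [5, 1, 3, 1]])
        start = counts.sum(axis=0) / counts.sum()
        reps = 2000
        totals = np.zeros(4)
        for _ in range(reps):
            out = imitation_step(counts, uniform_payoffs(2), make_cls(counts), 0.0, rng)
            totals += out.sum(axis=0) / out.sum()
        mean = totals / reps
        # per-period frequency jitter is < 0.5/16 per individual move;
        # 3 s.e. of the replicate mean stays well under 0.02
        assert np.abs(mean - start).max() < 0.02

    def test_between_group_mixing_spreads_strategies(self, rng):
        counts = np.array([[0, 4, 0, 0], [4, 0, 0, 0]])
        seen = 0
        for _ in range(300):
            out = imitation_step(counts, uniform_payoffs(2), make_cls(counts), 1.0, rng)
            seen += int(out[1, Strategy.CONTRIBUTOR] > 0)
        assert seen > 0  # with m=1 all models are external


class TestGroupConflict:
    def test_full_cooperators_always_beat_defectors(self, rng):
        counts = np.array([[0, 0, 4, 0], [4, 0, 0, 0]])
        for _ in range(200):
            out = group_conflict_step(counts, 1.0, rng)
            assert (out[:, Strategy.PUNISHER] == 4).all()

    @pytest.mark.parametrize(
        "group_i,group_j,expected",
        [
            # equal cooperator/defector fractions -> fair coin
            ([5, 5, 0, 0], [5, 1, 4, 0], 0.5),
            # 80% vs 20% cooperators -> initiator wins w.p. 0.8
            ([2, 8, 0, 0], [8, 2, 0, 0], 0.8),
            # full cooperators vs full defectors -> certain takeover
            ([0, 0, 10, 0], [10, 0, 0, 0], 1.0),
        ],
    )
    def test_takeover_probability_single_conflict(self, group_i, group_j, expected):
        # drive the engine with a stream where only group 0 initiates
        counts = np.array([group_i, group_j])

        class OneInitiator:
            """RNG facade: group 0 initiates, group 1 does not."""

            def __init__(self, seed):
                self._rng = np.random.default_rng(seed)
                self._calls = 0

            def random(self, size):
                self._calls += 1
                if self._calls % 2 == 1:  # u_init
                    return np.array([0.0, 1.0])
                return self._rng.random(size)  # u_win

            def integers(self, lo, hi, size):
                return np.zeros(size, dtype=np.int64)

            def permutation(self, N):
                return np.arange(N)

        rng = OneInitiator(7)
        wins = 0
        trials = 4000
        for _ in range(trials):
            out = group_conflict_step(counts, 0.5, rng)
            wins += int(
                (out[1] == counts[0]).all()
            )
        assert wins / trials == pytest.approx(expected, abs=0.03)

    def test_defector_and_cooperator_bias_agree_without_nonparticipants(self, rng):
        # d = 1 - x whenever z = 0, so the two rules give identical dynamics
        counts = np.array([[2, 3, 5, 0], [7, 2, 1, 0], [5, 5, 0, 0]])
        rng_a = np.random.default_rng(0)
        rng_b = np.random.default_rng(0)
        for _ in range(100):
            a = group_conflict_step(counts, 0.8, rng_a, bias="defectors")
            b = group_conflict_step(counts, 0.8, rng_b, bias="cooperators")
            assert (a == b).all()
            counts = a

    def test_population_conserved(self, rng):
        counts = np.array([[2, 3, 4, 1], [5, 5, 0, 0], [0, 0, 10, 0]])
        out = group_conflict_step(counts, 1.0, rng)
        assert (out.sum(axis=1) == 10).all()


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        counts = np.array([[2, 3, 4, 1]])
        out = mutation_step(counts, 0.0, True, rng)
        assert (out == counts).all()

    def test_certain_mutation_uniform_over_alternatives(self, rng):
        counts = np.array([[30, 0, 0, 0]])
        totals = np.zeros(4)
        reps = 2000
        for _ in range(reps):
            totals += mutation_step(counts, 1.0, True, rng)[0]
        mean = totals / reps
        assert mean[Strategy.DEFECTOR] == 0
        assert mean[1:] == pytest.approx([10, 10, 10], abs=0.5)

    def test_compulsory_never_creates_nonparticipants(self, rng):
        counts = np.array([[10, 5, 5, 0], [20, 0, 0, 0]])
        for _ in range(200):
            out = mutation_step(counts, 1.0, False, rng)
            assert out[:, Strategy.NONPARTICIPANT].sum() == 0
            assert (out.sum(axis=1) == 20).all()


class TestStep:
    def test_homogeneous_no_noise_fixed_point(self):
        params = ParamSet(
            N=4, n=8, scenario="voluntary", omega=0.9, e=0.0, m=0.0, mu=0.0, s=0.0,
            periods=10, burn_in=0,
        )
        counts = np.zeros((4, 4), dtype=np.int64)
        counts[:, Strategy.CONTRIBUTOR] = 8
        rngs = StageRNGs.from_seed(3)
        out = counts
        for t in range(10):
            out, rec = step(out, params, rngs, t)
            assert (out == counts).all()
            assert rec.freq_contributor == 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_every_stage_conserves_population(self, seed):
        params = ParamSet(
            N=4, n=6, scenario="voluntary", omega=0.9, e=0.1, m=0.2, mu=0.1, s=0.5,
            periods=5, burn_in=0,
        )
        rngs = StageRNGs.from_seed(seed)
        counts = init_population(params)
        for t in range(5):
            counts, rec = step(counts, params, rngs, t)
            check_state(counts, params)
            freqs = [
                rec.freq_defector,
                rec.freq_contributor,
                rec.freq_punisher,
                rec.freq_nonparticipant,
            ]
            assert sum(freqs) == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_compulsory_stays_compulsory(self, seed):
        params = ParamSet(
            N=4, n=6, scenario="compulsory", e=0.1, m=0.2, mu=0.5, s=0.5,
            periods=8, burn_in=0,
        )
        rngs = StageRNGs.from_seed(seed)
        counts = init_population(params)
        for t in range(8):
            counts, _ = step(counts, params, rngs, t)
            assert counts[:, Strategy.NONPARTICIPANT].sum() == 0

    def test_fixed_seed_reproduces_bitwise(self):
        params = ParamSet(
            N=8, n=10, scenario="voluntary", omega=0.9, periods=30, burn_in=0
        )
        a = run_simulation(params, 42)
        b = run_simulation(params, 42)
        assert (a.frequencies == b.frequencies).all()
        assert (a.final_counts == b.final_counts).all()

    def test_compulsory_trajectories_invariant_to_omega(self):
        # omega only enters through nonparticipants, which never exist here
        base = dict(N=8, n=10, scenario="compulsory", periods=40, burn_in=0)
        a = run_simulation(ParamSet(**base), 11)
        b = run_simulation(ParamSet(**base), 11)  # omega is None in both
        assert (a.frequencies == b.frequencies).all()

    def test_voluntary_without_mutation_matches_compulsory(self):
        # nonparticipation can only ever enter through mutation
        vol = ParamSet(
            N=8, n=10, scenario="voluntary", omega=1.2, mu=0.0, periods=40, burn_in=0
        )
        comp = ParamSet(N=8, n=10, scenario="compulsory", mu=0.0, periods=40, burn_in=0)
        a = run_simulation(vol, 5)
        b = run_simulation(comp, 5)
        assert (a.frequencies == b.frequencies).all()
        assert a.frequencies[:, Strategy.NONPARTICIPANT].sum() == 0

    def test_single_period_moves_frequencies_little(self):
        params = ParamSet(N=128, n=20, scenario="voluntary", omega=0.925, periods=1, burn_in=0)
        for seed in range(5):
            r = run_simulation(params, seed)
            coop = r.frequencies[0, 1] + r.frequencies[0, 2]
            # one period of imitation/conflict/mutation moves the global
            # frequency by at most a few takeovers plus ~mu of drift
            assert coop == pytest.approx(1 / 128, abs=0.03)
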