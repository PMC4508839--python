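"""Markov-chain construction, sampling, forward/backward conversion, entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hebbseq import markov as mk


def empirical_conditionals(states, n, direction="forward"):
    """Counting oracle: conditional transition frequencies from a sequence."""
    counts = np.zeros((n, n))
    for a, b in zip(states[:-1], states[1:]):
        if direction == "forward":
            counts[a, b] += 1
        else:
            counts[b, a] += 1  # row = current state, col = previous state
    sums = counts.sum(axis=1, keepdims=True)
    return counts / np.where(sums > 0, sums, 1)


class TestTransitionMatrix:
    def test_rejects_non_square_and_bad_rows(self):
        with pytest.raises(ValueError, match="square"):
            mk.TransitionMatrix(np.ones((2, 3)) / 3)
        with pytest.raises(ValueError, match="sums to"):
            mk.TransitionMatrix(np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mk.TransitionMatrix(np.array([[1.5, -0.5], [0.5, 0.5]]))

    def test_generators_are_row_stochastic(self):
        mats = [
            mk.make_gaussian_tm(19, 1.3),
            mk.make_mixed_tm(1.1),
            mk.make_birdsong_like_tm(8, 1.2, seed=4),
        ]
        for tm in mats:
            assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-9)
            assert tm.P.min() >= 0 and tm.P.max() <= 1


class TestStationaryDistribution:
    def test_uniform_two_state(self):
        pi = mk.stationary_distribution(mk.TransitionMatrix(np.full((2, 2), 0.5)))
        assert np.allclose(pi, [0.5, 0.5])

    def test_circulant_gaussian_is_uniform(self):
        pi = mk.stationary_distribution(mk.make_gaussian_tm(19, 1.7))
        assert np.allclose(pi, 1 / 19, atol=1e-9)

    def test_two_state_asymmetric_hand_solution(self):
        # pi P = pi for [[0.9, 0.1], [0.5, 0.5]] gives pi = (5/6, 1/6)
        pi = mk.stationary_distribution(mk.TransitionMatrix(np.array([[0.9, 0.1], [0.5, 0.5]])))
        assert np.allclose(pi, [5 / 6, 1 / 6], atol=1e-9)

    def test_reducible_chain_raises(self):
        with pytest.raises(ValueError, match="reducible"):
            mk.stationary_distribution(mk.TransitionMatrix(np.eye(3)))


class TestBackwardFromForward:
    def test_doubly_stochastic_gives_transpose(self):
        P = np.array([[0.6, 0.3, 0.1], [0.1, 0.6, 0.3], [0.3, 0.1, 0.6]])
        tm = mk.TransitionMatrix(P)
        assert np.allclose(mk.backward_from_forward(tm).P, P.T, atol=1e-9)

    def test_deterministic_cycle_reverses(self):
        P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        PB = mk.backward_from_forward(mk.TransitionMatrix(P)).P
        assert np.allclose(PB, P.T)

    def test_matches_empirical_backward_counts(self):
        tm = mk.TransitionMatrix(np.array([[0.9, 0.1], [0.5, 0.5]]))
        trace = mk.sample_sequence(tm, 10**6, seed=11)
        emp = empirical_conditionals(trace.states, 2, "backward")
        assert np.abs(mk.backward_from_forward(tm).P - emp).max() < 1e-2

    def test_time_reversal_is_an_involution(self, asym3_chain):
        PB = mk.backward_from_forward(asym3_chain)
        reversed_chain = mk.TransitionMatrix(PB.P, kind="forward")
        PF_again = mk.backward_from_forward(reversed_chain).P
        assert np.abs(PF_again - asym3_chain.P).max() < 1e-9

    def test_unreachable_state_raises(self):
        # state 2 is never entered: pi_2 = 0
        P = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="unreachable"):
            mk.backward_from_forward(mk.TransitionMatrix(P))


class TestSampleSequence:
    def test_deterministic_cycle(self):
        P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        trace = mk.sample_sequence(mk.TransitionMatrix(P), 6, seed=0, start=0)
        assert list(trace.states) == [0, 1, 2, 0, 1, 2]

    def test_empirical_frequencies_match(self, asym3_chain):
        trace = mk.sample_sequence(asym3_chain, 10**5, seed=3)
        emp = empirical_conditionals(trace.states, 3)
        assert np.abs(emp - asym3_chain.P).max() < 0.02

    def test_seed_reproducibility(self, asym3_chain):
        a = mk.sample_sequence(asym3_chain, 500, seed=9)
        b = mk.sample_sequence(asym3_chain, 500, seed=9)
        assert np.array_equal(a.states, b.states)


class TestGaussianFamily:
    def test_sigma_zero_is_deterministic_permutation(self):
        tm = mk.make_gaussian_tm(19, 0.0)
        assert set(np.unique(tm.P)) == {0.0, 1.0}
        for i in range(19):
            assert tm.P[i, (i + 9) % 19] == 1.0
            assert mk.row_entropy(tm.P[i]) == 0.0

    def test_large_sigma_approaches_uniform(self):
        tm = mk.make_gaussian_tm(19, 1e4)
        assert np.allclose(tm.P, 1 / 19, atol=1e-6)
        assert round(mk.mean_entropy(tm.P), 2) == 4.25

    def test_entropy_monotone_in_sigma(self):
        sigmas = [0.0, 0.3, 0.6, 1.0, 1.5, 2.5, 5.0, 20.0]
        ents = [mk.mean_entropy(mk.make_gaussian_tm(19, s).P) for s in sigmas]
        assert all(a <= b + 1e-12 for a, b in zip(ents, ents[1:]))

    @pytest.mark.parametrize("target", [0.0, 1.0, 2.2, 3.7, np.log2(19)])
    def test_solve_sigma_hits_entropy_target(self, target):
        sigma = mk.solve_sigma_for_entropy(target, 19)
        got = mk.row_entropy(mk.make_gaussian_tm(19, sigma).P[0])
        assert abs(got - target) < 1e-3

    def test_solve_sigma_rejects_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            mk.solve_sigma_for_entropy(np.log2(19) + 0.1, 19)


class TestMixedMatrix:
    def test_alternating_row_entropies(self):
        sigma = mk.solve_sigma_for_entropy(2.2)
        tm = mk.make_mixed_tm(sigma, 19)
        ents = np.array([mk.row_entropy(r) for r in tm.P])
        assert np.all(ents[::2] == 0.0)
        assert np.allclose(ents[1::2], 2.2, atol=1e-3)
        assert (ents == 0).sum() == 10 and (ents > 0).sum() == 9


class TestBirdsongGenerator:
    def test_zero_entropy_gives_unit_rows(self):
        tm = mk.make_birdsong_like_tm(6, 0.0, seed=1)
        assert np.allclose(np.sort(tm.P, axis=1)[:, -1], 1.0, atol=1e-9)

    @pytest.mark.parametrize("n,target", [(7, 1.5), (5, 0.5), (10, 2.2)])
    def test_mean_entropy_within_tolerance(self, n, target):
        tm = mk.make_birdsong_like_tm(n, target, seed=1)
        assert abs(mk.mean_entropy(tm.P) - target) < 0.1

    def test_seed_reproducibility(self):
        a = mk.make_birdsong_like_tm(7, 1.5, seed=3)
        b = mk.make_birdsong_like_tm(7, 1.5, seed=3)
        assert np.array_equal(a.P, b.P)


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (np.full(19, 1 / 19), 4.25),
            (np.array([0, 1.0, 0]), 0.0),
            (np.full(4, 0.25), 2.0),
        ],
    )
    def test_row_entropy_examples(self, p, expected):
        assert round(mk.row_entropy(p), 2) == expected

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            mk.row_entropy(np.array([-0.1, 1.1]))

    def test_profile_mean_consistency(self, gaussian_22):
        prof = mk.entropy_profile(gaussian_22)
        assert abs(prof.mean - prof.per_state.mean()) < 1e-12
        assert np.all(prof.per_state <= np.log2(19) + 1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
    def test_entropy_bounded_by_log_n(self, n, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(n))
        h = mk.row_entropy(p)
        assert -1e-12 <= h <= np.log2(n) + 1e-9
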