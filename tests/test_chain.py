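"""Birth–death projection, Moran fixation and the growth-class classifier."""

import itertools

import numpy as np
import pytest

from peakwalk import (
    CRITICAL,
    EXPONENTIAL,
    POLYNOMIAL,
    BirthDeathChain,
    MultiplicativeLandscape,
    SequenceSpace,
    classify_time_scale,
    equilibrium_distance,
    moran_fixation,
    neutral_chain,
    selection_chain,
)


def moran_fixation_absorbing_solve(r: float, N: int) -> float:
    """Oracle: absorption probability of the N-individual Moran chain.

    States = number of mutants 0..N; from i, a mutant reproduces w.p.
    i*r/(i*r + N - i) and the dying slot is uniform.  Solve the absorption
    system for the probability of reaching N from 1.
    """
    if N == 1:
        return 1.0
    up = np.zeros(N + 1)
    down = np.zeros(N + 1)
    for i in range(1, N):
        up[i] = (i * r / (i * r + N - i)) * ((N - i) / N)
        down[i] = ((N - i) / (i * r + N - i)) * (i / N)
    # h(i) = P(absorb at N); h(0)=0, h(N)=1
    A = np.zeros((N - 1, N - 1))
    b = np.zeros(N - 1)
    for i in range(1, N):
        A[i - 1, i - 1] = up[i] + down[i]
        if i > 1:
            A[i - 1, i - 2] = -down[i]
        if i < N - 1:
            A[i - 1, i - 1 + 1] = -up[i]
        if i == N - 1:
            b[i - 1] += up[i]
    return float(np.linalg.solve(A, b)[0])


class TestNeutralChain:
    def test_transition_probabilities_by_enumeration(self):
        """(down, stay, up) at k=1 for L=2, A=4 equals direct enumeration of
        the 6 point mutants of a distance-1 sequence."""
        space = SequenceSpace(2)
        center, s = "AA", "AC"  # distance 1
        moves = {"down": 0, "stay": 0, "up": 0}
        for r in space.neighbors(s):
            d = sum(a != b for a, b in zip(r, center))
            moves[{0: "down", 1: "stay", 2: "up"}[d]] += 1
        chain = neutral_chain(2, 4, 0)
        assert chain.p_down[1] == pytest.approx(moves["down"] / 6)
        assert chain.p_stay[1] == pytest.approx(moves["stay"] / 6)
        assert chain.p_up[1] == pytest.approx(moves["up"] / 6)
        assert (chain.p_down[1], chain.p_stay[1], chain.p_up[1]) == (
            pytest.approx(1 / 6),
            pytest.approx(1 / 3),
            pytest.approx(1 / 2),
        )

    def test_binary_alphabet_never_stays(self):
        chain = neutral_chain(10, 2, 0)
        assert np.all(chain.p_stay == 0)

    def test_no_up_from_farthest_shell(self):
        chain = neutral_chain(7, 4, 0)
        assert chain.p_up[7] == 0

    def test_rows_sum_to_one(self):
        for L, A in [(5, 2), (17, 4), (100, 4)]:
            chain = neutral_chain(L, A, 0)
            np.testing.assert_allclose(
                chain.p_down + chain.p_stay + chain.p_up, 1.0, atol=1e-12
            )

    def test_width_validation(self):
        with pytest.raises(ValueError):
            neutral_chain(5, 4, 5)


class TestMoranFixation:
    def test_neutral_limit(self):
        assert moran_fixation(1.0, 10) == pytest.approx(0.1)

    def test_two_individuals(self):
        # direct solve of the 2-individual absorption system gives 2/3
        assert moran_fixation(2.0, 2) == pytest.approx(2 / 3)
        assert moran_fixation_absorbing_solve(2.0, 2) == pytest.approx(2 / 3)

    def test_large_population_limit(self):
        assert moran_fixation(2.0, 10**6) == pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize("N", [2, 3, 4, 5])
    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_against_absorbing_chain_solve(self, N, r):
        assert moran_fixation(r, N) == pytest.approx(
            moran_fixation_absorbing_solve(r, N), abs=1e-12
        )

    def test_input_errors(self):
        with pytest.raises(ValueError):
            moran_fixation(-1.0, 5)
        with pytest.raises(ValueError):
            moran_fixation(1.0, 0)


class TestSelectionChain:
    def test_flat_profile_reproduces_neutral(self):
        chain = selection_chain(12, 4, 2, lambda k: 1.0, N=50)
        base = neutral_chain(12, 4, 2)
        np.testing.assert_allclose(chain.p_down, base.p_down, atol=1e-12)
        np.testing.assert_allclose(chain.p_up, base.p_up, atol=1e-12)

    def test_multiplicative_gradient_biases_inward(self):
        L, N = 20, 100
        land = MultiplicativeLandscape(SequenceSpace(L), "A" * L, 0.1, 0)
        chain = selection_chain(L, 4, 0, land.fitness_by_distance, N)
        base = neutral_chain(L, 4, 0)
        for k in range(1, L):
            assert (chain.p_down[k] / chain.p_up[k]) > (base.p_down[k] / base.p_up[k])

    def test_strong_selection_kills_uphill_moves(self):
        L = 10
        fit = {k: 1e12 ** (L - k) for k in range(L + 1)}
        chain = selection_chain(L, 4, 0, fit, N=100)
        assert np.all(chain.p_up[:L] < 1e-9)

    def test_zero_fitness_trap_flagged(self):
        with pytest.raises(ValueError):
            selection_chain(5, 4, 0, {0: 1, 1: 1, 2: 0, 3: 1, 4: 1, 5: 1}, N=10)


class TestEquilibriumDistance:
    @pytest.mark.parametrize(
        "A,L,expected", [(2, 10, 5), (4, 8, 6), (4, 100, 75)]
    )
    def test_examples(self, A, L, expected):
        assert equilibrium_distance(L, A) == expected

    def test_matches_argmax_of_shell_weights(self):
        import math

        for L, A in [(13, 4), (40, 4), (21, 2)]:
            weights = [math.comb(L, k) * (A - 1) ** k for k in range(L + 1)]
            assert equilibrium_distance(L, A) == int(np.argmax(weights))


class TestClassifier:
    def test_wide_target_polynomial(self):
        assert classify_time_scale(neutral_chain(40, 4, 34)) == POLYNOMIAL

    def test_narrow_target_exponential(self):
        assert classify_time_scale(neutral_chain(40, 4, 20)) == EXPONENTIAL

    def test_binary_alphabet_below_half(self):
        assert classify_time_scale(neutral_chain(40, 2, 10)) == EXPONENTIAL

    def test_invariant_under_time_rescaling(self):
        for w in (10, 20, 30, 35):
            chain = neutral_chain(40, 4, w)
            assert classify_time_scale(chain) == classify_time_scale(
                chain.rescaled(0.25)
            )

    def test_unreachable_flagged(self):
        chain = neutral_chain(5, 4, 0)
        broken = BirthDeathChain(
            5,
            0,
            np.where(np.arange(6) == 3, 0.0, chain.p_down),
            chain.p_stay + np.where(np.arange(6) == 3, chain.p_down, 0.0),
            chain.p_up,
        )
        from peakwalk import UnreachableTargetError

        with pytest.raises(UnreachableTargetError):
            classify_time_scale(broken)


def test_chain_row_validation():
    with pytest.raises(ValueError):
        BirthDeathChain(2, 0, [0.0, 0.5, 0.5], [0.0, 0.4, 0.5], [1.0, 0.2, 0.0])


def test_chain_csv_export(tmp_path):
    path = tmp_path / "chain.csv"
    neutral_chain(5, 4, 1).to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "k,p_down,p_stay,p_up"
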