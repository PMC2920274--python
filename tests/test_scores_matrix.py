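import numpy as np
import pytest

from conscore.alphabet import AA_INDEX, N_AA
from conscore.matrices import column_distribution
from conscore.scores import matrix as ms

A, W, V, I, S, D = (AA_INDEX[a] for a in "AWVISD")


def brute_force_sum_of_pairs(codes, M, pair_weights=None):
    """Explicit double loop over sequence pairs (independent oracle)."""
    n = len(codes)
    total, wsum, k = 0.0, 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            w = 1.0 if pair_weights is None else pair_weights[k]
            total += w * M[codes[i], codes[j]]
            wsum += w
            k += 1
    return total / wsum


class TestKarlin96:
    def test_conserved_is_one(self, matrices):
        assert ms.karlin96(np.full(5, W), matrices.M_K) == pytest.approx(1.0)

    def test_two_sequences_single_pair(self, matrices):
        assert ms.karlin96(np.array([A, W]), matrices.M_K) == pytest.approx(
            matrices.M_K[A, W]
        )

    def test_brute_force_small_columns(self, matrices):
        rng = np.random.default_rng(0)
        for _ in range(50):
            codes = rng.integers(0, N_AA, size=rng.integers(2, 7))
            assert ms.karlin96(codes, matrices.M_K) == pytest.approx(
                brute_force_sum_of_pairs(codes, matrices.M_K)
            )

    def test_identity_with_pei01sp(self, matrices):
        """karlin96 = (N * pei01sp - 1) / (N - 1): the two differ only by
        the inclusion of self pairs, an O(1/N) correction."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            codes = rng.integers(0, N_AA, size=n)
            p = column_distribution(codes)
            k = ms.karlin96(codes, matrices.M_K)
            pe = ms.pei01sp(p, matrices.M_K)
            assert k == pytest.approx((n * pe - 1.0) / (n - 1.0), abs=1e-10)


class TestSander91sp:
    def test_equal_weights_reduce_to_karlin(self, matrices):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, N_AA, size=6)
        n_pairs = 15
        w = np.full(n_pairs, 1.0 / n_pairs)
        assert ms.sander91sp(codes, matrices.M_K, w) == pytest.approx(
            ms.karlin96(codes, matrices.M_K)
        )

    def test_conserved_is_one_for_any_weights(self, matrices):
        w = np.array([0.5, 0.2, 0.3])
        assert ms.sander91sp(np.full(3, V), matrices.M_K, w) == pytest.approx(1.0)

    def test_duplicates_downweighted_toward_dedup_value(self, matrices):
        # sequences: two identical + one distant; distance-proportional pair
        # weights null out the duplicate pair entirely
        D = np.array([[0, 0, 80], [0, 0, 80], [80, 80, 0]], dtype=float)
        w = ms.sander91sp_pair_weights(D)
        codes = np.array([A, A, W])
        dedup = ms.karlin96(np.array([A, W]), matrices.M_K)
        assert ms.sander91sp(codes, matrices.M_K, w) == pytest.approx(dedup)

    def test_all_identical_sequences_fall_back_to_equal_weights(self, matrices):
        D = np.zeros((4, 4))
        w = ms.sander91sp_pair_weights(D)
        assert np.allclose(w, 1.0 / 6)

    def test_zero_weights_rejected(self, matrices):
        with pytest.raises(ValueError):
            ms.sander91sp(np.array([A, W]), matrices.M_K, np.zeros(1))


class TestValdar01:
    def test_high_self_similarity_residue_outranks(self, matrices):
        eq = np.full(6, 1 / 6)
        trp = ms.valdar01(np.full(6, W), matrices.M_V, eq)
        ala = ms.valdar01(np.full(6, A), matrices.M_V, eq)
        assert trp > ala

    def test_range(self, matrices):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            codes = rng.integers(0, N_AA, size=n)
            w = rng.dirichlet(np.ones(n))
            assert 0.0 <= ms.valdar01(codes, matrices.M_V, w) <= 1.0

    def test_brute_force_weighted_pairs(self, matrices):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            codes = rng.integers(0, N_AA, size=n)
            w = rng.dirichlet(np.ones(n))
            num = den = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    num += w[i] * w[j] * matrices.M_V[codes[i], codes[j]]
                    den += w[i] * w[j]
            assert ms.valdar01(codes, matrices.M_V, w) == pytest.approx(num / den)


class TestThompson97:
    def test_conserved_is_zero(self, matrices):
        w = np.full(4, 0.25)
        assert ms.thompson97(np.full(4, S), matrices.M, w) == pytest.approx(0.0)

    def test_two_sequence_closed_form(self, matrices):
        w = np.array([0.5, 0.5])
        codes = np.array([A, W])
        gap = np.linalg.norm(matrices.M[A] - matrices.M[W])
        assert ms.thompson97(codes, matrices.M, w) == pytest.approx(gap / 2)

    def test_permutation_invariant_under_equal_weights(self, matrices):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, N_AA, size=7)
        w = np.full(7, 1 / 7)
        perm = rng.permutation(7)
        assert ms.thompson97(codes, matrices.M, w) == pytest.approx(
            ms.thompson97(codes[perm], matrices.M, w)
        )


class TestMihalek07:
    def test_rare_substitution_outranks_common_with_same_majority(self, matrices):
        """With the majority residue held fixed, a rarer substitution has a
        smaller background pair probability and hence a larger relative
        entropy (the method's declared design)."""
        rare = ms.mihalek07(np.array([A] * 9 + [W]), matrices.M_M)
        common = ms.mihalek07(np.array([A] * 9 + [S]), matrices.M_M)
        assert rare > common

    def test_nonnegative_on_random_columns(self, matrices):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            codes = rng.integers(0, N_AA, size=n)
            assert ms.mihalek07(codes, matrices.M_M) >= -1e-12

    def test_pair_distribution_normalization(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            codes = rng.integers(0, N_AA, size=n)
            P = ms.pair_distribution(codes)
            iu = np.triu_indices(N_AA)
            mass = (P[iu] * np.where(iu[0] == iu[1], 1.0, 2.0)).sum()
            assert mass == pytest.approx(1.0)


class TestLiu08w:
    def test_conserved_hits_matrix_diagonal(self, matrices):
        w = np.full(5, 0.2)
        assert ms.liu08w(np.full(5, D), matrices.M_L, w) == pytest.approx(10.0)

    def test_range(self, matrices):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(2, 10))
            codes = rng.integers(0, N_AA, size=n)
            w = rng.dirichlet(np.ones(n))
            assert 2.0 <= ms.liu08w(codes, matrices.M_L, w) <= 10.0

    def test_tie_break_deterministic(self, matrices):
        # A and D tied at 50%: canonical order picks A as the reference
        codes = np.array([A, A, D, D])
        w = np.full(4, 0.25)
        expected = 0.5 * 10.0 + 0.5 * matrices.M_L[D, A]
        value = ms.liu08w(codes, matrices.M_L, w)
        assert value == pytest.approx(expected)
        assert value == ms.liu08w(codes[::-1].copy(), matrices.M_L, w)


class TestReorderingInvariance:
    def test_all_pair_scores_invariant_to_sequence_order(self, matrices):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, N_AA, size=6)
        perm = rng.permutation(6)
        assert ms.karlin96(codes, matrices.M_K) == pytest.approx(
            ms.karlin96(codes[perm], matrices.M_K)
        )
        p = column_distribution(codes)
        assert ms.pei01sp(p, matrices.M_K) == pytest.approx(
            ms.pei01sp(column_distribution(codes[perm]), matrices.M_K)
        )
        assert ms.mihalek07(codes, matrices.M_M) == pytest.approx(
            ms.mihalek07(codes[perm], matrices.M_M)
        )
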