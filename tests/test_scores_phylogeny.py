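import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from conscore.alphabet import AA_INDEX, N_AA
from conscore.scores import phylogeny
from conscore.scores.entropy import shannon_entropy, von_neumann_entropy

A, D, V, L, I, M = (AA_INDEX[a] for a in "ADVLIM")


def random_distance_matrix(rng, n):
    cond = rng.random(n * (n - 1) // 2) * 100 + 1
    return squareform(cond)


class TestUpgma:
    def test_two_leaves_join_at_half_distance(self):
        D = np.array([[0.0, 10.0], [10.0, 0.0]])
        tree = phylogeny.build_upgma(D)
        assert tree.merges == ((0, 1, 5.0),)

    def test_nearest_pair_joins_first(self):
        D = np.array([[0, 10, 50], [10, 0, 50], [50, 50, 0]], dtype=float)
        tree = phylogeny.build_upgma(D)
        assert tree.merges[0][:2] == (0, 1)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            phylogeny.build_upgma(D)

    def test_ultrametric_roundtrip(self):
        # a constructed ultrametric: ((0,1):10, 2):40 with leaf 3 at 80
        D = np.array(
            [
                [0, 10, 40, 80],
                [10, 0, 40, 80],
                [40, 40, 0, 80],
                [80, 80, 80, 0],
            ],
            dtype=float,
        )
        tree = phylogeny.build_upgma(D)
        heights = {frozenset(s): h for s, h in zip(tree.node_leafsets(), (m[2] for m in tree.merges))}
        assert heights[frozenset({0, 1})] == 5.0
        assert heights[frozenset({0, 1, 2})] == 20.0
        assert heights[frozenset({0, 1, 2, 3})] == 40.0

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 12))
            D = random_distance_matrix(rng, n)
            tree = phylogeny.build_upgma(D)
            Z = linkage(squareform(D, checks=False), method="average")
            assert np.allclose(
                sorted(h for _, _, h in tree.merges), sorted(Z[:, 2] / 2)
            )

    def test_cuts_match_cophenetic_thresholding(self):
        """Independent oracle for cut(n): leaves i, j share a group of
        cut(n) iff their cophenetic distance is below the (n-1)th highest
        merge height."""
        rng = np.random.default_rng(1)
        for _ in range(8):
            n = int(rng.integers(3, 13))
            D = random_distance_matrix(rng, n)
            tree = phylogeny.build_upgma(D)
            Z = linkage(squareform(D, checks=False), method="average")
            coph = squareform(cophenet(Z)) / 2.0
            heights = sorted((m[2] for m in tree.merges), reverse=True)
            for k in range(1, n + 1):
                cut = tree.cut(k)
                threshold = heights[k - 2] if k >= 2 else np.inf
                for group in cut:
                    for i in group:
                        for j in range(n):
                            together = j in group
                            assert together == (coph[i, j] < threshold - 1e-9 or i == j)

    def test_cuts_are_nested_refinements(self):
        rng = np.random.default_rng(2)
        D = random_distance_matrix(rng, 9)
        tree = phylogeny.build_upgma(D)
        assert tree.cut(1) == [frozenset(range(9))]
        assert len(tree.cut(9)) == 9
        for k in range(1, 9):
            coarse, fine = tree.cut(k), tree.cut(k + 1)
            for group in fine:
                assert any(group <= big for big in coarse)

    def test_newick_export_parses(self):
        import io

        from Bio import Phylo

        D = np.array([[0, 10, 50], [10, 0, 50], [50, 50, 0]], dtype=float)
        tree = phylogeny.build_upgma(D)
        parsed = Phylo.read(io.StringIO(tree.to_newick(["a", "b", "c"])), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["a", "b", "c"]


class TestEvolutionaryTrace:
    def star_tree(self, n):
        D = np.full((n, n), 50.0)
        np.fill_diagonal(D, 0.0)
        return phylogeny.build_upgma(D)

    def test_conserved_column_is_zero(self):
        tree = self.star_tree(4)
        assert phylogeny.mihalek04(np.full(4, A), tree) == 0.0
        assert phylogeny.zhang08(np.full(4, A), tree, np.eye(N_AA)) == 0.0

    def test_two_sequences_single_term(self):
        tree = self.star_tree(2)
        value = phylogeny.mihalek04(np.array([A, D]), tree)
        assert value == pytest.approx(np.log(2))

    def test_term_by_term_against_cut_oracle(self, matrices):
        """Recompute the trace independently: iterate cuts 1..N-1 and sum
        group entropies explicitly from tree.cut(n)."""
        rng = np.random.default_rng(3)
        for _ in range(6):
            n = int(rng.integers(3, 9))
            D = random_distance_matrix(rng, n)
            tree = phylogeny.build_upgma(D)
            codes = rng.integers(0, N_AA, size=n)
            expected_s = 0.0
            expected_v = 0.0
            for cut_n in range(1, n):
                for group in tree.cut(cut_n):
                    idx = sorted(group)
                    p = np.bincount(codes[idx], minlength=N_AA) / len(idx)
                    expected_s += shannon_entropy(p, base=np.e) / cut_n
                    expected_v += von_neumann_entropy(
                        p, matrices.M_f, base=np.e
                    ) / cut_n
            assert phylogeny.mihalek04(codes, tree) == pytest.approx(expected_s)
            assert phylogeny.zhang08(codes, tree, matrices.M_f) == pytest.approx(
                expected_v
            )

    def test_clade_confined_variation_scores_lower(self):
        dist = np.array(
            [[0, 10, 80, 80], [10, 0, 80, 80], [80, 80, 0, 10], [80, 80, 10, 0]],
            dtype=float,
        )
        tree = phylogeny.build_upgma(dist)
        confined = phylogeny.mihalek04(np.array([A, A, D, D]), tree)
        scattered = phylogeny.mihalek04(np.array([A, D, A, D]), tree)
        assert confined < scattered

    def test_zhang_discounts_similar_residues(self, matrices):
        tree = self.star_tree(4)
        codes = np.array([V, L, I, M])
        assert phylogeny.zhang08(codes, tree, matrices.M_f) < phylogeny.mihalek04(
            codes, tree
        )

    def test_identity_matrix_reduction(self, matrices):
        tree = self.star_tree(5)
        rng = np.random.default_rng(4)
        codes = rng.integers(0, N_AA, size=5)
        assert phylogeny.zhang08(codes, tree, np.eye(N_AA)) == pytest.approx(
            phylogeny.mihalek04(codes, tree), abs=1e-9
        )

    def test_per_sequence_variant_is_monotone_rescale(self):
        tree = self.star_tree(6)
        rng = np.random.default_rng(5)
        codes = rng.integers(0, N_AA, size=6)
        assert phylogeny.mihalek04(codes, tree, per_sequence=True) == pytest.approx(
            phylogeny.mihalek04(codes, tree) / 5.0
        )

    def test_relabeling_preserving_distances_preserves_score(self):
        rng = np.random.default_rng(6)
        n = 7
        D = random_distance_matrix(rng, n)
        codes = rng.integers(0, N_AA, size=n)
        perm = rng.permutation(n)
        D_perm = D[np.ix_(perm, perm)]
        assert phylogeny.mihalek04(codes[perm], phylogeny.build_upgma(D_perm)) == (
            pytest.approx(phylogeny.mihalek04(codes, phylogeny.build_upgma(D)))
        )


class TestRate4SiteAdapter:
    def test_missing_executable_skips_method(self):
        from conscore.scoring import build_registry

        assert phylogeny.mayrose04_adapter(None, None) is None
        registry = build_registry()
        assert "mayrose04" not in registry
        assert len(registry) == 23
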