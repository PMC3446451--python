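import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from seroarray.clustering import (
    DistanceMatrix,
    cut_tree,
    euclidean_distances,
    heatmap_export,
    to_newick,
    upgma,
)


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, max(2, n - 1)))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"L{i}" for i in range(n)], d)


def naive_upgma_heights(d):
    """O(n^3) recompute-all-cross-pairs reference; returns merge heights."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or avg < best[0]:
                best = (avg, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestEuclideanDistances:
    def test_3_4_5_triangle(self):
        df = pd.DataFrame([[0, 0, 0], [3, 4, 0]], index=["a", "b"], columns=list("xyz"))
        dm = euclidean_distances(df, axis="antigens")
        assert dm.d[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1, 2], [1, 2], [9, 9]], index=list("abc"), columns=["s1", "s2"])
        assert euclidean_distances(df, "antigens").d[0, 1] == 0.0

    def test_matches_sum_of_squares_oracle(self, rng):
        x = rng.normal(size=(5, 4))
        df = pd.DataFrame(x, index=list("abcde"), columns=list("wxyz"))
        dm = euclidean_distances(df, "antigens")
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((x[i] - x[j]) ** 2).sum())
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_missing_values_imputed_with_row_median(self):
        df = pd.DataFrame(
            [[1.0, np.nan, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"], columns=["s1", "s2", "s3"]
        )
        dm = euclidean_distances(df, "antigens")
        assert dm.d[0, 1] == pytest.approx(0.0)  # nan -> median(1,3) = 2

    def test_single_item_axis_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="at least 2"):
            euclidean_distances(df, "antigens")


class TestUpgma:
    def test_worked_example_0_1_5(self):
        pts = np.array([0.0, 1.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :])
        tree = upgma(DistanceMatrix(["a", "b", "c"], d))
        assert [m.height for m in tree.merges] == [1.0, 4.5]
        assert tree.merges[0].size == 2 and tree.merges[1].size == 3

    def test_two_leaves(self):
        tree = upgma(DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]])))
        assert len(tree.merges) == 1 and tree.merges[0].height == 3.0

    def test_matches_naive_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 8))
            dm = random_distance_matrix(rng, n)
            tree = upgma(dm)
            assert np.allclose(
                [m.height for m in tree.merges], naive_upgma_heights(dm.d), atol=1e-12
            )

    def test_matches_scipy_average_linkage(self, rng):
        for n in (5, 12, 30):
            dm = random_distance_matrix(rng, n)
            tree = upgma(dm)
            z = linkage(squareform(dm.d, checks=False), method="average")
            assert np.allclose([m.height for m in tree.merges], z[:, 2], atol=1e-10)

    def test_heights_non_decreasing_and_sizes_sum(self, rng):
        dm = random_distance_matrix(rng, 15)
        tree = upgma(dm)
        h = [m.height for m in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))
        assert tree.merges[-1].size == 15

    def test_permutation_invariant_heights(self, rng):
        dm = random_distance_matrix(rng, 10)
        perm = rng.permutation(10)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)])
        h1 = [m.height for m in upgma(dm).merges]
        h2 = [m.height for m in upgma(dm2).merges]
        assert np.allclose(h1, h2, atol=1e-12)

    def test_deterministic_tie_break_on_equidistant_points(self):
        d = np.array([[0.0, 2.0, 2.0], [2.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        tree = upgma(DistanceMatrix(["b", "a", "c"], d))
        first = tree.merges[0]
        # lexicographically smallest label pair (a, b) merges first
        assert {tree.labels[first.a], tree.labels[first.b]} == {"a", "b"}

    def test_ultrametric_three_point_condition(self, rng):
        dm = random_distance_matrix(rng, 8)
        coph = upgma(dm).cophenetic()
        for i, j, k in itertools.combinations(range(8), 3):
            assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-12

    def test_cophenetic_fixed_point_on_ultrametric_input(self, rng):
        coph = upgma(random_distance_matrix(rng, 7)).cophenetic()
        tree2 = upgma(DistanceMatrix([f"L{i}" for i in range(7)], coph))
        assert np.allclose(tree2.cophenetic(), coph, atol=1e-12)

    def test_leaf_order_keeps_subtrees_contiguous(self, rng):
        dm = random_distance_matrix(rng, 12)
        tree = upgma(dm)
        pos = {lab: i for i, lab in enumerate(tree.leaf_order)}
        n = tree.n_leaves
        for node in range(n, n + len(tree.merges)):
            spots = sorted(pos[tree.labels[i]] for i in tree.node_leaves(node))
            assert spots == list(range(spots[0], spots[0] + len(spots)))


class TestCutTree:
    def test_trivial_cuts(self, rng):
        dm = random_distance_matrix(rng, 6)
        tree = upgma(dm)
        assert set(cut_tree(tree, 1).values()) == {0}
        assert len(set(cut_tree(tree, 6).values())) == 6

    def test_recovers_planted_patient_groups(self, study_sim, study_cohort):
        _, cohort = study_cohort
        dm = euclidean_distances(cohort.fluid_columns("PL"), axis="samples")
        cut = cut_tree(upgma(dm), 2)
        truth = [study_sim.truth.patient_groups[s[:-2]] for s in cut]
        assert adjusted_rand_score(truth, [cut[s] for s in cut]) == 1.0


class TestExport:
    def _parse_heights(self, newick, n_leaves):
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        depths = tree.depths()
        total = max(d for c, d in depths.items() if c.is_terminal())
        return sorted(
            2 * (total - d) for c, d in depths.items() if not c.is_terminal()
        )

    def test_newick_round_trips_merge_heights(self, rng):
        dm = random_distance_matrix(rng, 9)
        tree = upgma(dm)
        parsed = self._parse_heights(to_newick(tree), 9)
        assert np.allclose(parsed, sorted(m.height for m in tree.merges), atol=1e-6)

    def test_identity_ordered_matrix_round_trip(self, rng, tmp_path):
        df = pd.DataFrame(
            [[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["s1", "s2"]
        )
        row_tree = upgma(euclidean_distances(df, "antigens"))
        col_tree = upgma(euclidean_distances(df, "samples"))
        paths = heatmap_export(df, row_tree, col_tree, tmp_path / "hm")
        out = pd.read_csv(paths["matrix"], sep="\t", index_col=0)
        assert list(out.index) == row_tree.leaf_order
        assert list(out.columns) == col_tree.leaf_order
        assert np.allclose(out.loc[df.index, df.columns].to_numpy(), df.to_numpy())

    def test_reordered_rows_follow_leaf_order(self, rng, tmp_path):
        x = rng.normal(size=(8, 4))
        df = pd.DataFrame(x, index=[f"A{i}" for i in range(8)], columns=list("wxyz"))
        row_tree = upgma(euclidean_distances(df, "antigens"))
        col_tree = upgma(euclidean_distances(df, "samples"))
        paths = heatmap_export(df, row_tree, col_tree, tmp_path / "hm")
        out = pd.read_csv(paths["matrix"], sep="\t", index_col=0)
        assert list(out.index) == row_tree.leaf_order
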