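import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from islandbeta.core_io import DomainError
from islandbeta.functional import (
    functional_tree,
    gower_per_trait,
    optimize_weights,
    upgma,
)


def traits_frame(values: dict) -> pd.DataFrame:
    return pd.DataFrame(values, index=[f"sp{i}" for i in range(len(next(iter(values.values()))))])


class TestGower:
    def test_range_normalization(self):
        d = gower_per_trait(traits_frame({"forearm_length": [0.0, 5.0, 10.0]}))
        m = d["forearm_length"].to_numpy()
        assert m[0, 1] == pytest.approx(0.5)
        assert m[1, 2] == pytest.approx(0.5)
        assert m[0, 2] == pytest.approx(1.0)
        assert np.all(np.diag(m) == 0)

    def test_identical_values_zero_distance(self):
        d = gower_per_trait(traits_frame({"aspect_ratio": [6.0, 6.0, 7.0]}))
        assert d["aspect_ratio"].iloc[0, 1] == 0.0

    def test_constant_trait_dropped_with_warning(self):
        tf = traits_frame({"forearm_length": [1.0, 2.0, 3.0], "aspect_ratio": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_per_trait(tf)
        assert list(d) == ["forearm_length"]


class TestOptimizeWeights:
    def test_identical_matrices_split_evenly(self, rng):
        x = rng.random(6)
        m = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        td = optimize_weights({"a": m, "b": m.copy()})
        assert td.weights.to_numpy() == pytest.approx([0.5, 0.5], abs=1e-6)
        assert td.objective_sd == pytest.approx(0.0, abs=1e-12)

    def test_exchangeable_traits_near_equal_weights(self, rng):
        # two traits drawn from the same distribution are symmetric in the
        # objective, so the optimum stays near equal weights
        xs = [rng.random(10) for _ in range(2)]
        ds = {
            f"t{i}": pd.DataFrame(np.abs(x[:, None] - x[None, :]) / np.ptp(x))
            for i, x in enumerate(xs)
        }
        td = optimize_weights(ds)
        assert abs(td.weights.iloc[0] - 0.5) < 0.05

    def test_duplicated_trait_matches_grid_search_oracle(self, rng):
        from islandbeta.functional import _equal_contribution_objective, _upper

        x1, x2 = rng.random(8), rng.random(8)
        d1 = np.abs(x1[:, None] - x1[None, :]) / np.ptp(x1)
        d2 = np.abs(x2[:, None] - x2[None, :]) / np.ptp(x2)
        ds = {"a": pd.DataFrame(d1), "b": pd.DataFrame(d2), "c": pd.DataFrame(d1.copy())}
        td = optimize_weights(ds)
        vecs = np.array([_upper(m.to_numpy()) for m in ds.values()])
        # exhaustive simplex grid at 0.01 steps
        best = np.inf
        for w1 in np.arange(0.01, 0.99, 0.01):
            for w2 in np.arange(0.01, 1.0 - w1, 0.01):
                w3 = 1.0 - w1 - w2
                if w3 < 0.01:
                    continue
                best = min(best, _equal_contribution_objective(np.array([w1, w2, w3]), vecs))
        assert td.objective_sd <= best + 1e-4

    def test_never_worse_than_equal_weights(self, rng):
        from islandbeta.functional import _equal_contribution_objective, _upper

        ds = {}
        for i in range(4):
            x = rng.random(9)
            ds[f"t{i}"] = pd.DataFrame(np.abs(x[:, None] - x[None, :]) / np.ptp(x))
        td = optimize_weights(ds)
        vecs = np.array([_upper(m.to_numpy()) for m in ds.values()])
        equal = _equal_contribution_objective(np.full(4, 0.25), vecs)
        assert td.objective_sd <= equal + 1e-12


class TestUpgma:
    def tree_abc(self):
        D = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        return upgma(D)

    def test_hand_agglomeration(self):
        tree = self.tree_abc()
        assert tree.heights == [1.0, 2.0]
        coph = tree.cophenetic()
        assert coph.loc["A", "B"] == pytest.approx(2.0)
        assert coph.loc["A", "C"] == pytest.approx(4.0)

    def test_equal_distances_constant_cophenetic(self):
        D = pd.DataFrame(2.0 * (1 - np.eye(4)), index=list("ABCD"), columns=list("ABCD"))
        coph = upgma(D).cophenetic().to_numpy()
        off = coph[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_two_leaves(self):
        D = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma(D)
        assert tree.heights == [1.5]

    def test_non_symmetric_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(DomainError, match="symmetric"):
            upgma(D)

    def test_ultrametric_inequality(self, rng):
        n = 12
        M = rng.random((n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"s{i}" for i in range(n)]
        coph = upgma(pd.DataFrame(D, index=labels, columns=labels)).cophenetic().to_numpy()
        worst = 0.0
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    worst = max(worst, coph[i, k] - max(coph[i, j], coph[j, k]))
        assert worst <= 1e-9

    def test_matches_scipy_average_linkage(self, rng):
        # independent oracle on a tie-free random matrix
        n = 10
        M = rng.random((n, n)) + np.arange(n)[:, None] * 1e-3
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"s{i}" for i in range(n)]
        ours = upgma(pd.DataFrame(D, index=labels, columns=labels)).cophenetic().to_numpy()
        theirs = squareform(cophenet(average(squareform(D))))
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_tie_break_prefers_lexicographic_smallest(self):
        # three equidistant pairs: (A,B) merges first by label order
        D = pd.DataFrame(
            1.0 * (1 - np.eye(3)), index=["C", "A", "B"], columns=["C", "A", "B"]
        )
        tree = upgma(D)
        first = tree.children[0]
        merged = sorted(tree.labels[i] for i in first)
        assert merged == ["A", "B"]


def test_functional_tree_newick_parses(rng):
    traits = pd.DataFrame(
        {
            "forearm_length": rng.normal(40, 5, 6),
            "aspect_ratio": rng.normal(6, 1, 6),
            "relative_wing_loading": rng.normal(1, 0.2, 6),
            "wing_tip_shape_index": rng.normal(1.5, 0.3, 6),
        },
        index=[f"sp{i}" for i in range(6)],
    )
    tree, td = functional_tree(traits)
    import dendropy

    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(traits.index)
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    coph = tree.cophenetic()
    for a in traits.index[:3]:
        for b in traits.index[3:]:
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(coph.loc[a, b], abs=1e-6)
    assert td.weights.sum() == pytest.approx(1.0)
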