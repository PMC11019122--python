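"""Trait distances and the functional dendrogram.

Species are placed in a functional space spanned by four continuous wing
variables (forearm length, aspect ratio, relative wing loading, wing tip
shape index).  Pairwise functional distance is a weighted Gower distance
whose per-trait weights are optimized so that every trait correlates
equally with the combined distance — the "equal contribution" criterion
popularised by the gawdis approach.  The combined distance feeds an
average-linkage (UPGMA) agglomeration that yields the ultrametric
functional tree used by the branch-length form of beta diversity.

The UPGMA implementation is local because the analysis contracts on an
explicit tie-break (merge the pair whose lexicographically smallest
member id is smallest) and on the height convention (merge height equals
half the average inter-cluster distance, so cophenetic distance equals
the average distance).  A test cross-checks it against SciPy's
average-linkage on tie-free inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_io import TRAIT_COLUMNS, DomainError


@dataclass
class TraitDistance:
    """Weighted Gower distance with its per-trait weights and contributions."""

    matrix: pd.DataFrame
    weights: pd.Series
    correlations: pd.Series  # r_k = cor(d_k, D) per trait
    objective_sd: float  # achieved SD of the r_k
    converged: bool = True


@dataclass
class Dendrogram:
    """Rooted ultrametric tree from agglomerative clustering.

    Leaves are 0..n-1 in the order of ``labels``; internal node ``n+m``
    records the m-th merge.  ``heights`` are tip-to-node depths, so the
    cophenetic distance between two leaves is twice the height of their
    lowest common ancestor.
    """

    labels: list[str]
    children: list[tuple[int, int]]  # per internal node
    heights: list[float]  # per internal node, in merge order

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> list[set[int]]:
        """Leaf index set below every node (leaves first, then merges)."""
        n = self.n_leaves
        sets: list[set[int]] = [{i} for i in range(n)]
        for a, b in self.children:
            sets.append(sets[a] | sets[b])
        return sets

    def cophenetic(self) -> pd.DataFrame:
        n = self.n_leaves
        out = np.zeros((n, n))
        sets = self.leaf_sets()
        for (a, b), h in zip(self.children, self.heights):
            for i in sets[a]:
                for j in sets[b]:
                    out[i, j] = out[j, i] = 2.0 * h
        return pd.DataFrame(out, index=self.labels, columns=self.labels)

    def node_heights(self) -> list[float]:
        return [0.0] * self.n_leaves + list(self.heights)

    def branches(self) -> list[tuple[int, int, float]]:
        """(parent, child, length) for every edge below the root."""
        parent_height = self.node_heights()
        out = []
        for m, (a, b) in enumerate(self.children):
            node = self.n_leaves + m
            h = self.heights[m]
            out.append((node, a, h - parent_height[a]))
            out.append((node, b, h - parent_height[b]))
        return out

    def cut(self, k: int) -> pd.Series:
        """Cluster membership after undoing the last k-1 merges.

        Ties in merge height resolve toward the earlier merge because the
        cut is taken in merge order, not by a height threshold.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise DomainError(f"cannot cut {n}-leaf dendrogram into {k} groups")
        keep = len(self.children) - (k - 1)
        sets = self.leaf_sets()
        roots = set(range(n))
        for m in range(keep):
            a, b = self.children[m]
            roots -= {a, b}
            roots.add(n + m)
        labels = np.empty(n, dtype=int)
        for cid, r in enumerate(sorted(roots)):
            for leaf in sets[r]:
                labels[leaf] = cid
        return pd.Series(labels, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        heights = self.node_heights()

        def rec(node: int) -> str:
            if node < self.n_leaves:
                return self.labels[node]
            a, b = self.children[node - self.n_leaves]
            h = heights[node]
            return (
                f"({rec(a)}:{h - heights[a]:.10g},{rec(b)}:{h - heights[b]:.10g})"
            )

        return rec(len(heights) - 1) + ";"


FunctionalTree = Dendrogram


def gower_per_trait(traits: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Range-normalized absolute-difference matrix per continuous trait.

    d_k(i, j) = |x_ik - x_jk| / (max_k - min_k), so each matrix lives in
    [0, 1].  A trait with zero range carries no information and is dropped
    with a warning.
    """
    cols = [c for c in TRAIT_COLUMNS if c in traits.columns]
    if not cols:
        cols = list(traits.columns)
    out: dict[str, pd.DataFrame] = {}
    for c in cols:
        x = traits[c].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise DomainError(f"non-finite values in trait {c!r}")
        rng = x.max() - x.min()
        if rng == 0:
            warnings.warn(f"trait {c!r} has zero range and was dropped")
            continue
        d = np.abs(x[:, None] - x[None, :]) / rng
        out[c] = pd.DataFrame(d, index=traits.index, columns=traits.index)
    if not out:
        raise DomainError("all traits have zero range")
    return out


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _equal_contribution_objective(w: np.ndarray, vecs: np.ndarray) -> float:
    combined = w @ vecs
    sd = combined.std()
    if sd == 0:
        return 0.0
    c = combined - combined.mean()
    v = vecs - vecs.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(v, axis=1) * np.linalg.norm(c)
    r = (v @ c) / np.where(denom == 0, np.inf, denom)
    return float(np.std(r))


def optimize_weights(
    d_matrices: dict[str, pd.DataFrame],
    w_min: float = 0.01,
    n_starts: int = 8,
    seed: int = 0,
) -> TraitDistance:
    """Weights making every trait contribute equally to the combined distance.

    Minimizes the standard deviation of the Pearson correlations between
    each per-trait distance vector and the weighted combination, over the
    simplex {w_k in [w_min, 1], sum w = 1}.  Multi-start SLSQP from the
    equal-weight point plus seeded random simplex draws keeps the result
    deterministic for a given seed.
    """
    names = list(d_matrices)
    if len(names) < 2:
        raise DomainError("need at least two trait distance matrices")
    vecs = np.array([_upper(d_matrices[n].to_numpy(dtype=float)) for n in names])
    k = len(names)

    rng = np.random.default_rng(seed)
    starts = [np.full(k, 1.0 / k)]
    starts += list(rng.dirichlet(np.ones(k), size=n_starts - 1))

    bounds = [(w_min, 1.0)] * k
    constraint = {"type": "eq", "fun": lambda w: w.sum() - 1.0}
    best_w, best_val, ok = starts[0], np.inf, False
    for s in starts:
        s = np.clip(s, w_min, 1.0)
        s = s / s.sum()
        res = minimize(
            _equal_contribution_objective,
            s,
            args=(vecs,),
            method="SLSQP",
            bounds=bounds,
            constraints=[constraint],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        val = _equal_contribution_objective(res.x, vecs)
        if val < best_val - 1e-15:
            best_val, best_w, ok = val, res.x, bool(res.success)
    equal = np.full(k, 1.0 / k)
    if _equal_contribution_objective(equal, vecs) <= best_val:
        best_w, best_val, ok = equal, _equal_contribution_objective(equal, vecs), True
    if not ok:
        warnings.warn("weight optimizer did not converge; returning best candidate")

    w = best_w / best_w.sum()
    combined = np.zeros_like(next(iter(d_matrices.values())).to_numpy(dtype=float))
    for wi, n in zip(w, names):
        combined = combined + wi * d_matrices[n].to_numpy(dtype=float)
    cvec = w @ vecs
    corrs = []
    for row in vecs:
        if row.std() == 0 or cvec.std() == 0:
            corrs.append(np.nan)
        else:
            corrs.append(float(np.corrcoef(row, cvec)[0, 1]))
    idx = next(iter(d_matrices.values())).index
    return TraitDistance(
        matrix=pd.DataFrame(combined, index=idx, columns=idx),
        weights=pd.Series(w, index=names, name="weight"),
        correlations=pd.Series(corrs, index=names, name="r"),
        objective_sd=best_val,
        converged=ok,
    )


def upgma(distance: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    Merge height is half the average inter-cluster distance, so the
    cophenetic distance between two clusters equals their average
    distance.  Equal-distance ties merge the pair containing the
    lexicographically smallest member id (then the smallest id of the
    partner cluster).
    """
    D = distance.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise DomainError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12) or np.any(D < -1e-12):
        raise DomainError("distance matrix must be non-negative with zero diagonal")
    labels = [str(x) for x in distance.index]
    n = len(labels)
    if n < 2:
        raise DomainError("need at least two items to cluster")

    # active cluster -> (node id, size, lexicographically smallest member)
    active: dict[int, tuple[int, int, str]] = {
        i: (i, 1, labels[i]) for i in range(n)
    }
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    children: list[tuple[int, int]] = []
    heights: list[float] = []
    next_node = n
    keys = list(active)
    while len(keys) > 1:
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                d = dist[frozenset((i, j))]
                mi, mj = active[i][2], active[j][2]
                tie = tuple(sorted((mi, mj)))
                cand = (d, tie, i, j)
                if best is None or cand < best:
                    best = cand
        d, _, i, j = best
        ni, nj = active[i][1], active[j][1]
        merged_size = ni + nj
        for k_ in keys:
            if k_ in (i, j):
                continue
            dik = dist.pop(frozenset((i, k_)))
            djk = dist.pop(frozenset((j, k_)))
            dist[frozenset((next_node, k_))] = (ni * dik + nj * djk) / merged_size
        dist.pop(frozenset((i, j)))
        children.append((active[i][0], active[j][0]))
        heights.append(d / 2.0)
        active[next_node] = (
            next_node,
            merged_size,
            min(active[i][2], active[j][2]),
        )
        del active[i], active[j]
        keys = [k_ for k_ in keys if k_ not in (i, j)] + [next_node]
        next_node += 1
    return Dendrogram(labels=labels, children=children, heights=heights)


def functional_tree(
    traits: pd.DataFrame, w_min: float = 0.01, seed: int = 0
) -> tuple[Dendrogram, TraitDistance]:
    """Optimized weighted Gower distance and its UPGMA tree in one call."""
    d_list = gower_per_trait(traits)
    if len(d_list) == 1:
        (name, mat), = d_list.items()
        td = TraitDistance(
            matrix=mat,
            weights=pd.Series([1.0], index=[name], name="weight"),
            correlations=pd.Series([1.0], index=[name], name="r"),
            objective_sd=0.0,
        )
    else:
        td = optimize_weights(d_list, w_min=w_min, seed=seed)
    return upgma(td.matrix), td
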