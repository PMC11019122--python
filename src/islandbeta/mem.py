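"""Spatial weight matrices and Moran's eigenvector maps (MEMs).

Spatial structure enters the variation partitioning through MEMs: the
eigenvectors of the doubly centered spatial weight matrix of a neighbor
graph over the site centroids.  Four graph constructions are supported
(Delaunay triangulation, Gabriel graph, relative neighborhood graph,
minimum spanning tree); eigenvectors with positive eigenvalue describe
positively autocorrelated spatial patterns from broad to fine scale.
Forward selection with the double stopping rule (candidate permutation
p-value and the global model's adjusted R²) picks the significant MEMs,
and the graph whose selected set explains the response best (highest
adjusted R²) becomes the spatial factor set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError

from .core_io import DomainError, Site
from .ordination import adjusted_r2, pcoa_axes, predictor_q, r_squared

GRAPH_METHODS = ("delaunay", "gabriel", "relative_neighborhood", "mst")
EARTH_RADIUS_KM = 6371.0088


def great_circle_km(sites: Sequence[Site]) -> np.ndarray:
    """Pairwise haversine distances between site centroids, in km."""
    lat = np.radians([s.lat for s in sites])
    lon = np.radians([s.lon for s in sites])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _project(sites: Sequence[Site]) -> np.ndarray:
    """Equirectangular projection (km) used for the planar graph predicates."""
    lat = np.array([s.lat for s in sites])
    lon = np.array([s.lon for s in sites])
    k = 111.32
    return np.column_stack(
        [lon * k * np.cos(np.radians(lat.mean())), lat * k]
    )


@dataclass
class SpatialGraph:
    """Undirected neighbor graph over sites with great-circle edge lengths."""

    site_ids: list[str]
    method: str
    edges: list[tuple[int, int]]
    distances_km: np.ndarray
    weight_style: Literal["binary", "inverse_distance"] = "binary"

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def weight_matrix(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, j in self.edges:
            w = 1.0 if self.weight_style == "binary" else 1.0 / self.distances_km[i, j]
            W[i, j] = W[j, i] = w
        return W

    def is_connected(self) -> bool:
        W = self.weight_matrix()
        ncomp, _ = connected_components(W > 0, directed=False)
        return ncomp == 1


def build_graph(
    sites: Sequence[Site],
    method: str,
    weight_style: str = "binary",
    duplicate_policy: Literal["error", "jitter"] = "error",
) -> SpatialGraph:
    """Neighbor graph by one of the four standard constructions.

    Gabriel: edge (i, j) iff no third point lies inside the circle with
    diameter ij.  Relative neighborhood: iff no k with
    max(d(i,k), d(j,k)) < d(i,j).  The predicates run on a planar
    equirectangular projection (which also feeds the Delaunay
    triangulation, preserving the RNG ⊆ Gabriel ⊆ Delaunay hierarchy);
    reported edge lengths are great-circle km.
    """
    if method not in GRAPH_METHODS:
        raise DomainError(f"unknown graph method {method!r}")
    pts = _project(sites)
    n = len(sites)
    if n < 2:
        raise DomainError("need at least two sites")
    uniq = {tuple(np.round(p, 9)) for p in pts}
    if len(uniq) < n:
        if duplicate_policy == "error":
            raise DomainError("duplicate site coordinates; set duplicate_policy='jitter'")
        rng = np.random.default_rng(0)
        pts = pts + rng.normal(0, 1e-6, pts.shape)

    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    edges: list[tuple[int, int]] = []
    if method == "delaunay":
        if n < 3:
            raise DomainError("Delaunay needs at least three sites")
        try:
            tri = Delaunay(pts)
        except QhullError as err:
            raise DomainError(f"degenerate (collinear?) site geometry: {err}") from None
        seen = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    e = tuple(sorted((int(simplex[a]), int(simplex[b]))))
                    seen.add(e)
        edges = sorted(seen)
    elif method == "mst":
        D = great_circle_km(sites)
        T = minimum_spanning_tree(D).toarray()
        edges = sorted(tuple(sorted((int(i), int(j)))) for i, j in zip(*np.nonzero(T)))
    else:
        for i in range(n):
            for j in range(i + 1, n):
                others = [k for k in range(n) if k not in (i, j)]
                if method == "gabriel":
                    ok = all(d2[i, k] + d2[j, k] >= d2[i, j] - 1e-12 for k in others)
                else:  # relative neighborhood
                    ok = all(
                        max(d2[i, k], d2[j, k]) >= d2[i, j] - 1e-12 for k in others
                    )
                if ok:
                    edges.append((i, j))

    return SpatialGraph(
        site_ids=[s.site_id for s in sites],
        method=method,
        edges=edges,
        distances_km=great_circle_km(sites),
        weight_style=weight_style,  # type: ignore[arg-type]
    )


@dataclass
class MEMBasis:
    """Orthonormal, centered spatial eigenvectors with their eigenvalues."""

    vectors: pd.DataFrame  # sites x MEMs, eigenvalue-descending
    eigenvalues: np.ndarray
    moran_i: np.ndarray
    method: str

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def mem_eigenvectors(
    graph: SpatialGraph, mode: Literal["positive", "all"] = "positive"
) -> MEMBasis:
    """Moran's eigenvector maps of a spatial weight matrix.

    Eigen-decomposes H W H with H = I - 11'/n; eigenvalues within 1e-9 of
    zero are discarded, and by default only positive-eigenvalue vectors
    (positive spatial autocorrelation) are retained.  Moran's I of each
    vector is (n / sum W) * (v' W v) / (v' v).
    """
    n = graph.n
    if n < 3:
        raise DomainError("need at least three sites for MEMs")
    W = graph.weight_matrix()
    if W.sum() == 0:
        raise DomainError("graph has no edges")
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ W @ H
    M = (M + M.T) / 2.0
    lam, V = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    keep = np.abs(lam) > 1e-9
    if mode == "positive":
        keep &= lam > 0
    lam, V = lam[keep], V[:, keep]
    # sign convention: first nonzero entry positive, for reproducibility
    for c in range(V.shape[1]):
        nz = np.nonzero(np.abs(V[:, c]) > 1e-12)[0]
        if len(nz) and V[nz[0], c] < 0:
            V[:, c] = -V[:, c]
    wsum = W.sum()
    moran = np.array(
        [n / wsum * (V[:, c] @ W @ V[:, c]) / (V[:, c] @ V[:, c]) for c in range(V.shape[1])]
    )
    cols = [f"MEM{c + 1}" for c in range(V.shape[1])]
    return MEMBasis(
        vectors=pd.DataFrame(V, index=graph.site_ids, columns=cols),
        eigenvalues=lam,
        moran_i=moran,
        method=graph.method,
    )


@dataclass
class SelectionResult:
    selected: list[str]
    adj_r2: float  # adjusted R2 of the selected set (0.0 when empty)
    global_p: float
    global_adj_r2: float
    step_p: dict[str, float] = field(default_factory=dict)


def forward_select(
    response: pd.DataFrame | np.ndarray,
    basis: MEMBasis,
    alpha: float = 0.05,
    nperm: int = 999,
    seed: int = 0,
) -> SelectionResult:
    """Forward selection of MEMs with the double stopping rule.

    The response is a site dissimilarity matrix; its principal
    coordinates are regressed on the candidates.  Selection starts only
    if the global model (all candidates) is significant under row
    permutation; candidates are then added by largest gain in R² until
    the best candidate's permutation p exceeds alpha or the cumulative
    adjusted R² would exceed the global model's adjusted R².
    """
    if basis.m == 0:
        return SelectionResult([], 0.0, 1.0, 0.0)
    D = response.to_numpy(dtype=float) if isinstance(response, pd.DataFrame) else np.asarray(response, float)
    Y = pcoa_axes(D)
    n = Y.shape[0]
    X = basis.vectors.to_numpy()
    names = list(basis.vectors.columns)
    rng = np.random.default_rng(seed)

    q_all = predictor_q(X, names)
    r2_all = r_squared(Y, q_all)
    global_adj = adjusted_r2(r2_all, n, q_all.shape[1])
    perm_r2 = np.empty(nperm)
    for b in range(nperm):
        perm_r2[b] = r_squared(Y[rng.permutation(n)], q_all)
    global_p = float((np.sum(perm_r2 >= r2_all) + 1) / (nperm + 1))
    if global_p > alpha:
        return SelectionResult([], 0.0, global_p, global_adj)

    selected: list[int] = []
    step_p: dict[str, float] = {}
    cur_adj = 0.0
    remaining = list(range(len(names)))
    while remaining:
        best_j, best_r2, best_q = None, -np.inf, None
        for j in remaining:
            cols = selected + [j]
            q = predictor_q(X[:, cols], [names[c] for c in cols])
            r2 = r_squared(Y, q)
            if r2 > best_r2:
                best_j, best_r2, best_q = j, r2, q
        cand_adj = adjusted_r2(best_r2, n, len(selected) + 1)
        if cand_adj > global_adj + 1e-10:  # tolerance guards exact-fit responses
            break
        perm = np.empty(nperm)
        for b in range(nperm):
            perm[b] = r_squared(Y[rng.permutation(n)], best_q)
        p = float((np.sum(perm >= best_r2) + 1) / (nperm + 1))
        step_p[names[best_j]] = p
        if p > alpha:
            break
        selected.append(best_j)
        cur_adj = cand_adj
        remaining.remove(best_j)
    return SelectionResult(
        selected=[names[j] for j in selected],
        adj_r2=cur_adj if selected else 0.0,
        global_p=global_p,
        global_adj_r2=global_adj,
        step_p=step_p,
    )


@dataclass
class SWMChoice:
    method: str
    graph: SpatialGraph
    basis: MEMBasis
    selection: SelectionResult

    @property
    def spatial_predictors(self) -> pd.DataFrame:
        return self.basis.vectors[self.selection.selected]


def choose_swm(
    response: pd.DataFrame,
    sites: Sequence[Site],
    methods: Sequence[str] = GRAPH_METHODS,
    weight_style: str = "binary",
    alpha: float = 0.05,
    nperm: int = 999,
    seed: int = 0,
) -> SWMChoice:
    """Best spatial weight matrix among the candidate graph constructions.

    Each method's significant MEMs are found by forward selection; the
    method whose selected set attains the highest adjusted R² wins, ties
    going to the earlier method in canonical order (delaunay, gabriel,
    relative_neighborhood, mst).  If no method selects anything, the
    first method is returned with an empty spatial factor set and a
    warning.
    """
    if not methods:
        raise DomainError("no graph methods supplied")
    best: SWMChoice | None = None
    for method in methods:
        graph = build_graph(sites, method, weight_style=weight_style)
        basis = mem_eigenvectors(graph)
        sel = forward_select(response, basis, alpha=alpha, nperm=nperm, seed=seed)
        cand = SWMChoice(method=method, graph=graph, basis=basis, selection=sel)
        if best is None:
            best = cand
        elif cand.selection.selected and (
            not best.selection.selected
            or cand.selection.adj_r2 > best.selection.adj_r2 + 1e-12
        ):
            best = cand
    assert best is not None
    if not best.selection.selected:
        warnings.warn("no spatial eigenvectors selected by any graph method")
    return best
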