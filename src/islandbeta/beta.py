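"""Pairwise beta diversity with replacement / richness-difference partitioning.

For a pair of assemblages let ``a`` be the shared diversity and ``b``,
``c`` the diversity unique to each side.  With Jaccard denominators the
total pairwise dissimilarity decomposes additively:

    beta_total = (b + c) / (a + b + c)
    beta_repl  = 2 * min(b, c) / (a + b + c)      (species replacement)
    beta_rich  = |b - c| / (a + b + c)            (richness difference)

In taxonomic mode a, b, c are species counts.  In functional mode they
are branch lengths of the functional tree spanned by both, only the
first, or only the second community, where a community spans every branch
on the root-to-tip path of each of its species.  On a star tree with unit
branches the two modes coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core_io import CommunityMatrix, DomainError
from .functional import Dendrogram


@dataclass
class BetaTriplet:
    """Three site x site dissimilarity matrices with beta_total = beta_repl + beta_rich."""

    total: pd.DataFrame
    repl: pd.DataFrame
    rich: pd.DataFrame
    mode: Literal["taxonomic", "functional"]

    def __post_init__(self) -> None:
        resid = (
            self.total.to_numpy() - self.repl.to_numpy() - self.rich.to_numpy()
        )
        if np.abs(resid).max() > 1e-12:
            raise DomainError("beta_total != beta_repl + beta_rich")

    def component(self, name: str) -> pd.DataFrame:
        return {"total": self.total, "repl": self.repl, "rich": self.rich}[name]


def _triplet_from_abc(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, index, mode: str
) -> BetaTriplet:
    denom = a + b + c
    if np.any(denom[~np.eye(len(index), dtype=bool)] <= 0):
        raise DomainError("a site pair shares no diversity at all (a+b+c = 0)")
    denom = np.where(denom == 0, 1.0, denom)  # diagonal only
    total = (b + c) / denom
    repl = 2.0 * np.minimum(b, c) / denom
    rich = np.abs(b - c) / denom
    for m in (total, repl, rich):
        np.fill_diagonal(m, 0.0)
    mk = lambda m: pd.DataFrame(m, index=index, columns=index)
    return BetaTriplet(total=mk(total), repl=mk(repl), rich=mk(rich), mode=mode)


def beta_taxonomic(cm: CommunityMatrix) -> BetaTriplet:
    """Jaccard-family partitioned beta diversity on presence/absence data."""
    X = cm.values()
    a = X @ X.T
    richness = X.sum(axis=1)
    b = richness[:, None] - a
    c = richness[None, :] - a
    return _triplet_from_abc(a, b, c, cm.occurrence.index, "taxonomic")


def beta_functional(cm: CommunityMatrix, tree: Dendrogram) -> BetaTriplet:
    """Branch-length beta diversity on the functional tree.

    Every branch below the root carries its length; a community spans a
    branch when at least one of its species sits below it.  a, b, c are
    the summed lengths of branches spanned by both communities, only the
    first, and only the second.
    """
    tip_index = {lab: i for i, lab in enumerate(tree.labels)}
    missing = [sp for sp in cm.species if sp not in tip_index]
    if missing:
        raise DomainError(f"species missing from the functional tree: {missing}")

    leaf_sets = tree.leaf_sets()
    branches = tree.branches()
    lengths = np.array([ln for _, _, ln in branches])
    # branch x species incidence restricted to community species
    n_sp = len(cm.species)
    inc = np.zeros((len(branches), n_sp), dtype=bool)
    col_of = {sp: j for j, sp in enumerate(cm.species)}
    for bi, (_, child, _) in enumerate(branches):
        for leaf in leaf_sets[child]:
            sp = tree.labels[leaf]
            j = col_of.get(sp)
            if j is not None:
                inc[bi, j] = True

    X = cm.values()  # sites x species
    spanned = (X @ inc.T.astype(float)) > 0  # sites x branches
    S = spanned.astype(float)
    a = (S * lengths) @ S.T
    totals = S @ lengths
    b = totals[:, None] - a
    c = totals[None, :] - a
    return _triplet_from_abc(a, b, c, cm.occurrence.index, "functional")


def summarize_beta(bt: BetaTriplet) -> pd.DataFrame:
    """Mean and sample SD of each component over the strict lower triangle."""
    n = bt.total.shape[0]
    if n < 2:
        raise DomainError("need at least two sites to summarize beta diversity")
    il = np.tril_indices(n, k=-1)
    rows = {}
    for name in ("total", "repl", "rich"):
        v = bt.component(name).to_numpy()[il]
        rows[name] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
    return pd.DataFrame(rows).T[["mean", "sd"]]
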