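"""Distance-based RDA and three-set variation partitioning.

The variation in a site dissimilarity matrix is decomposed over three
predictor sets — spatial (selected MEMs, ``S``), environmental (``E``)
and historical (``H``) — into seven adjusted-R² fractions (three unique,
three pairwise-shared, one three-way shared) plus a residual, by
inclusion–exclusion over the adjusted R² of the seven nested dbRDA
models.  Shared fractions may be negative (suppression); the seven
fractions always sum to the adjusted R² of the full model.

Significance is assessed with a permutation null that breaks the
site-to-predictor linkage: permuting the rows of the community matrix
and recomputing the dissimilarity matrix is equivalent to permuting the
rows and columns of the observed dissimilarity jointly, which in turn
only permutes the rows of its principal coordinates — the cheap route
used here (the equivalence is covered by a test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beta import beta_functional, beta_taxonomic
from .core_io import CommunityMatrix, DomainError, FactorSet, Site, filter_scale
from .functional import functional_tree
from .mem import GRAPH_METHODS, SWMChoice, choose_swm
from .ordination import (
    adjusted_r2,
    drop_constant_columns,
    pcoa_axes,
    predictor_q,
    r_squared,
)

FRACTION_KEYS = (
    "S|(E∩H)",
    "E|(S∩H)",
    "H|(S∩E)",
    "S∩E|H",
    "S∩H|E",
    "E∩H|S",
    "E∩S∩H",
)
TOTAL_KEYS = ("Total S", "Total E", "Total H")
MODEL_KEYS = ("S", "E", "H", "SE", "SH", "EH", "SEH")


@dataclass
class OrdinationModel:
    """One dbRDA fit: principal coordinates regressed on predictors."""

    r2: float
    adj_r2: float
    n: int
    p: int
    axes: np.ndarray = field(repr=False)


def dbrda(D: pd.DataFrame | np.ndarray, X: pd.DataFrame | np.ndarray) -> OrdinationModel:
    """Distance-based redundancy analysis of D on the predictor matrix X.

    D is square-root transformed and double-centered into principal
    coordinates; R² is the share of the coordinate cloud's total sum of
    squares captured by least-squares projection on the centered
    predictors, and the adjustment is the classical
    1 - (1-R²)(n-1)/(n-p-1).
    """
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    Y = pcoa_axes(Dm)
    Q = predictor_q(X)
    n, p = Y.shape[0], Q.shape[1]
    if n <= p + 1:
        raise DomainError(f"n = {n} sites cannot support p = {p} predictors")
    r2 = r_squared(Y, Q)
    return OrdinationModel(r2=r2, adj_r2=adjusted_r2(r2, n, p), n=n, p=p, axes=Y)


@dataclass
class VarpartResult:
    """Seven adjusted-R² fractions, residual, per-set totals, optional p-values."""

    fractions: dict[str, float]
    residual: float
    totals: dict[str, float]
    p_values: dict[str, float] | None = None
    nperm: int = 0
    response: str = ""
    scale: str = ""

    def as_series(self) -> pd.Series:
        out = dict(self.fractions)
        out.update(self.totals)
        out["Residuals"] = self.residual
        return pd.Series(out)


def fractions_from_r2(r2: Mapping[str, float]) -> tuple[dict[str, float], float, dict[str, float]]:
    """Inclusion–exclusion over the seven model adjusted R² values.

    ``r2`` maps "S", "E", "H", "SE", "SH", "EH", "SEH" to adjusted R².
    Returns (fractions, residual, totals); the fractions sum to
    r2["SEH"] by construction.
    """
    missing = [k for k in MODEL_KEYS if k not in r2]
    if missing:
        raise DomainError(f"missing model R2 values: {missing}")
    full = r2["SEH"]
    s_u = full - r2["EH"]
    e_u = full - r2["SH"]
    h_u = full - r2["SE"]
    se = full - r2["H"] - s_u - e_u
    sh = full - r2["E"] - s_u - h_u
    eh = full - r2["S"] - e_u - h_u
    seh = full - (s_u + e_u + h_u + se + sh + eh)
    fractions = dict(
        zip(FRACTION_KEYS, (s_u, e_u, h_u, se, sh, eh, seh))
    )
    totals = {"Total S": r2["S"], "Total E": r2["E"], "Total H": r2["H"]}
    return fractions, 1.0 - full, totals


def _model_qs(
    X_S: pd.DataFrame, X_E: pd.DataFrame, X_H: pd.DataFrame
) -> dict[str, np.ndarray]:
    blocks = {"S": X_S, "E": X_E, "H": X_H}
    qs: dict[str, np.ndarray] = {}
    for key in MODEL_KEYS:
        parts = [blocks[c].to_numpy(dtype=float) for c in key]
        qs[key] = predictor_q(
            np.hstack(parts), [f"{c}:{col}" for c in key for col in blocks[c].columns]
        )
    return qs


def _fractions_for_axes(
    Y: np.ndarray, qs: Mapping[str, np.ndarray]
) -> tuple[dict[str, float], float, dict[str, float]]:
    n = Y.shape[0]
    r2 = {}
    for key, Q in qs.items():
        p = Q.shape[1]
        if n <= p + 1:
            raise DomainError(f"n = {n} sites cannot support p = {p} predictors ({key})")
        r2[key] = adjusted_r2(r_squared(Y, Q), n, p)
    return fractions_from_r2(r2)


def varpart3(
    D: pd.DataFrame | np.ndarray,
    X_S: pd.DataFrame,
    X_E: pd.DataFrame,
    X_H: pd.DataFrame,
    response: str = "",
    scale: str = "",
) -> VarpartResult:
    """Three-set variation partitioning of a dissimilarity matrix."""
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    Y = pcoa_axes(Dm)
    qs = _model_qs(X_S, X_E, X_H)
    fractions, residual, totals = _fractions_for_axes(Y, qs)
    closure = abs(sum(fractions.values()) - (1.0 - residual))
    if closure > 1e-9:
        raise AssertionError(f"fraction closure violated by {closure:.2e}")
    return VarpartResult(
        fractions=fractions, residual=residual, totals=totals,
        response=response, scale=scale,
    )


def permutation_test(
    D: pd.DataFrame | np.ndarray,
    X_S: pd.DataFrame,
    X_E: pd.DataFrame,
    X_H: pd.DataFrame,
    nperm: int = 9999,
    seed: int = 0,
    response: str = "",
    scale: str = "",
) -> VarpartResult:
    """Row-permutation significance of every fraction and total.

    Each iteration permutes the site rows of the community matrix —
    realized as a joint row/column permutation of D, i.e. a row
    permutation of its principal coordinates — recomputes all seven
    model adjusted R² values, and re-derives the fractions.  p = (number
    of permuted values >= observed + 1) / (nperm + 1), so p is strictly
    positive with floor 1/(nperm+1).
    """
    if nperm < 1:
        raise DomainError("nperm must be >= 1")
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    Y = pcoa_axes(Dm)
    qs = _model_qs(X_S, X_E, X_H)
    fr_obs, residual, tot_obs = _fractions_for_axes(Y, qs)

    keys = list(FRACTION_KEYS) + list(TOTAL_KEYS)
    obs = {**fr_obs, **tot_obs}
    count = dict.fromkeys(keys, 0)
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    for _ in range(nperm):
        fr_p, _, tot_p = _fractions_for_axes(Y[rng.permutation(n)], qs)
        for k in FRACTION_KEYS:
            count[k] += fr_p[k] >= obs[k]
        for k in TOTAL_KEYS:
            count[k] += tot_p[k] >= obs[k]
    p_values = {k: (count[k] + 1) / (nperm + 1) for k in keys}
    return VarpartResult(
        fractions=fr_obs, residual=residual, totals=tot_obs,
        p_values=p_values, nperm=nperm, response=response, scale=scale,
    )


# ---------------------------------------------------------------------------
# full analysis table


RESPONSES = tuple(
    (mode, comp)
    for mode in ("taxonomic", "functional")
    for comp in ("total", "repl", "rich")
)


def _spatial_block(choice: SWMChoice) -> pd.DataFrame:
    """Selected MEMs, falling back to the broadest-scale eigenvector.

    The three-set partition needs a nonempty spatial block; when forward
    selection retains nothing, the first (broadest, most autocorrelated)
    eigenvector is kept so the fractions stay defined — its contribution
    is then expected to be judged nonsignificant by the permutation test.
    """
    X = choice.spatial_predictors
    if X.shape[1] == 0:
        X = choice.basis.vectors.iloc[:, :1]
    return X


def run_table1(
    cm: CommunityMatrix,
    sites: Sequence[Site],
    traits: pd.DataFrame,
    factors: FactorSet,
    scales: Sequence[str] = ("entire", "main_islands"),
    responses: Sequence[tuple[str, str]] = RESPONSES,
    nperm: int = 9999,
    swm_nperm: int = 999,
    alpha: float = 0.05,
    methods: Sequence[str] = GRAPH_METHODS,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Variation partitioning of every response at every scale.

    For each scale the community is filtered, taxonomic and functional
    beta triplets computed, spatial predictors chosen per response
    (graph selection + MEM forward selection), and the partition plus its
    permutation test run.  Returns a long-format table (scale, mode,
    component, fraction, adj_r2, p) and a log of choices made.
    """
    rows = []
    log: dict = {}
    for scale in scales:
        cm_s, sites_s, dropped = filter_scale(cm, sites, scale)
        tree, td = functional_tree(traits.loc[cm_s.species], seed=seed)
        triplets = {
            "taxonomic": beta_taxonomic(cm_s),
            "functional": beta_functional(cm_s, tree),
        }
        env, env_dropped = drop_constant_columns(
            factors.environmental.loc[[s.site_id for s in sites_s]]
        )
        hist, hist_dropped = drop_constant_columns(
            factors.historical.loc[[s.site_id for s in sites_s]]
        )
        log[scale] = {
            "dropped_species": dropped,
            "dropped_env": env_dropped,
            "dropped_hist": hist_dropped,
            "responses": {},
        }
        for mode, comp in responses:
            D = triplets[mode].component(comp)
            choice = choose_swm(
                D, sites_s, methods=methods, alpha=alpha, nperm=swm_nperm, seed=seed
            )
            X_S = _spatial_block(choice)
            res = permutation_test(
                D, X_S, env, hist, nperm=nperm, seed=seed,
                response=f"{mode}_{comp}", scale=scale,
            )
            log[scale]["responses"][f"{mode}_{comp}"] = {
                "swm": choice.method,
                "selected_mems": choice.selection.selected,
                "model_adj_r2_full": 1.0 - res.residual,
            }
            for key in list(FRACTION_KEYS) + list(TOTAL_KEYS):
                value = res.fractions.get(key, res.totals.get(key))
                rows.append(
                    {
                        "scale": scale,
                        "mode": mode,
                        "component": comp,
                        "fraction": key,
                        "adj_r2": value,
                        "p": res.p_values[key],
                    }
                )
            rows.append(
                {
                    "scale": scale,
                    "mode": mode,
                    "component": comp,
                    "fraction": "Residuals",
                    "adj_r2": res.residual,
                    "p": np.nan,
                }
            )
    return pd.DataFrame(rows), log
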