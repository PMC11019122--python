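"""Domain types, CSV readers/writers, mesh-grid arithmetic and scale filtering.

The sampling unit of the analysis is either a primary mesh cell of the
Japanese national grid system (1 degree of longitude by 40 minutes of
latitude, roughly 6400 km^2) or a whole minor island.  Sites carry a
biogeographical region label (``HKD`` north of the Tsugaru Strait, ``HSK``
between the two straits, ``NNS`` south of the Tokara Strait) and a flag
marking the four large main islands, which defines the reduced spatial
scale of the analysis.

All tabular interchange is UTF-8 CSV with the identifier in the first
column.  Missing covariate values propagate as NaN; downstream ordination
refuses to run on missing predictors rather than imputing silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

REGIONS = ("HKD", "HSK", "NNS")
SITE_KINDS = ("grid", "island")
SCALES = ("entire", "main_islands")

TRAIT_COLUMNS = (
    "forearm_length",
    "aspect_ratio",
    "relative_wing_loading",
    "wing_tip_shape_index",
)

ENV_COLUMNS = (
    "mean_annual_temperature",
    "annual_precipitation",
    "mean_elevation",
    "mean_slope",
    "area_km2",
    "residential_ratio",
    "plantation_ratio",
)

HIST_COLUMNS = (
    "dT_BA_YD",
    "dP_BA_YD",
    "dT_YD_current",
    "dP_YD_current",
    "tsugaru",
    "tokara",
)


class DomainError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Site:
    """One sampling unit: a mesh grid cell or a whole minor island."""

    site_id: str
    kind: Literal["grid", "island"]
    lon: float
    lat: float
    region: Literal["HKD", "HSK", "NNS"]
    on_main_island: bool
    area_km2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SITE_KINDS:
            raise DomainError(f"unknown site kind {self.kind!r}")
        if self.region not in REGIONS:
            raise DomainError(f"unknown region {self.region!r}")
        if not (-180.0 <= self.lon <= 180.0):
            raise DomainError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise DomainError(f"latitude {self.lat} outside [-90, 90]")
        if self.area_km2 < 0:
            raise DomainError("area_km2 must be non-negative")


@dataclass
class CommunityMatrix:
    """Sites x species presence/absence matrix.

    ``occurrence`` is an integer 0/1 DataFrame whose index holds site ids
    and whose columns hold species ids.  Every analyzed site must host at
    least one species (pairwise dissimilarity is undefined for an empty
    assemblage).
    """

    occurrence: pd.DataFrame

    def __post_init__(self) -> None:
        occ = self.occurrence
        if occ.index.has_duplicates or occ.columns.has_duplicates:
            raise DomainError("duplicate site or species ids")
        vals = occ.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DomainError("occurrence values must be 0/1")
        empty = occ.index[vals.sum(axis=1) == 0]
        if len(empty):
            raise DomainError(f"all-zero site rows: {list(empty)}")
        self.occurrence = occ.astype(np.int8)

    @property
    def sites(self) -> list[str]:
        return list(self.occurrence.index)

    @property
    def species(self) -> list[str]:
        return list(self.occurrence.columns)

    def values(self) -> np.ndarray:
        return self.occurrence.to_numpy(dtype=float)

    def richness(self) -> pd.Series:
        return self.occurrence.sum(axis=1)


@dataclass
class FactorSet:
    """Per-site environmental, historical and (optional) spatial predictors.

    Rows of every block align with one shared site ordering.  The two
    strait indicators in the historical block are strict 0/1: ``tsugaru``
    marks sites north of the Tsugaru Strait, ``tokara`` marks sites south
    of the Tokara Strait.
    """

    environmental: pd.DataFrame
    historical: pd.DataFrame
    spatial: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.environmental.index.equals(self.historical.index):
            raise DomainError("environmental/historical site orderings differ")
        for col in ("tsugaru", "tokara"):
            if col in self.historical.columns:
                v = self.historical[col].to_numpy()
                if not np.isin(v, (0, 1)).all():
                    raise DomainError(f"{col} indicator must be exactly 0/1")

    def aligned_to(self, site_ids: Sequence[str]) -> "FactorSet":
        spatial = None if self.spatial is None else self.spatial.loc[list(site_ids)]
        return FactorSet(
            environmental=self.environmental.loc[list(site_ids)],
            historical=self.historical.loc[list(site_ids)],
            spatial=spatial,
        )


# ---------------------------------------------------------------------------
# mesh-code arithmetic


def latlon_to_mesh1(lat: float, lon: float) -> int:
    """Primary mesh code (JIS X 0410) of the cell containing (lat, lon).

    The cell spans 40 minutes of latitude by 1 degree of longitude and is
    closed on its lower-left corner, open on the upper-right, so every
    point maps to exactly one code: ``floor(lat * 1.5) * 100 + (floor(lon)
    - 100)``.  Only the Japanese domain (lat in (20, 50), lon in
    (120, 150)) is accepted.
    """
    if not (20.0 < lat < 50.0 and 120.0 < lon < 150.0):
        raise DomainError(f"({lat}, {lon}) outside the supported mesh domain")
    return int(math.floor(lat * 1.5)) * 100 + (int(math.floor(lon)) - 100)


def aggregate_to_sites(
    fine_grid: pd.DataFrame,
    sites: Sequence[Site],
    value_col: str = "value",
) -> pd.Series:
    """Mean of fine-grid point values within each site cell.

    ``fine_grid`` needs ``lat``/``lon`` columns plus the value column;
    rows may instead carry an explicit ``site_id`` (used for island
    sites, whose membership is an identity match, not a mesh lookup).
    Sites containing no points get NaN, never a silent zero.
    """
    assignments: dict[str, list[float]] = {s.site_id: [] for s in sites}
    mesh_to_site: dict[int, str] = {}
    for s in sites:
        if s.kind == "grid":
            code = latlon_to_mesh1(s.lat, s.lon)
            if code in mesh_to_site:
                raise DomainError(f"two grid sites share mesh code {code}")
            mesh_to_site[code] = s.site_id

    has_id = "site_id" in fine_grid.columns
    for row in fine_grid.itertuples(index=False):
        sid = None
        if has_id and isinstance(getattr(row, "site_id", None), str):
            sid = row.site_id
            if sid not in assignments:
                continue
        else:
            try:
                code = latlon_to_mesh1(row.lat, row.lon)
            except DomainError:
                continue
            sid = mesh_to_site.get(code)
        if sid is not None:
            assignments[sid].append(float(getattr(row, value_col)))

    out = {
        sid: (float(np.mean(v)) if v else np.nan) for sid, v in assignments.items()
    }
    return pd.Series(out, name=value_col).reindex([s.site_id for s in sites])


def filter_scale(
    cm: CommunityMatrix,
    sites: Sequence[Site],
    scale: Literal["entire", "main_islands"],
) -> tuple[CommunityMatrix, list[Site], list[str]]:
    """Restrict the community to one spatial scale.

    ``entire`` keeps everything; ``main_islands`` keeps only sites flagged
    ``on_main_island``.  Species columns that become all-zero are dropped
    and their ids returned, so the caller can report what fell out of the
    analyzed pool.  Occurrence values of retained site x species pairs are
    never altered.
    """
    if scale not in SCALES:
        raise DomainError(f"unknown scale {scale!r}")
    by_id = {s.site_id: s for s in sites}
    missing = [sid for sid in cm.sites if sid not in by_id]
    if missing:
        raise DomainError(f"sites absent from the site table: {missing}")
    if scale == "entire":
        kept = [by_id[sid] for sid in cm.sites]
        occ = cm.occurrence
    else:
        kept = [by_id[sid] for sid in cm.sites if by_id[sid].on_main_island]
        occ = cm.occurrence.loc[[s.site_id for s in kept]]
    if len(kept) < 4:
        raise DomainError(
            f"{len(kept)} sites remain at scale {scale!r}; ordination needs >= 4"
        )
    dropped = [sp for sp in occ.columns if occ[sp].sum() == 0]
    occ = occ.drop(columns=dropped)
    return CommunityMatrix(occ), kept, dropped


# ---------------------------------------------------------------------------
# CSV interchange


def sites_to_frame(sites: Sequence[Site]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "kind": [s.kind for s in sites],
            "lon": [s.lon for s in sites],
            "lat": [s.lat for s in sites],
            "region": [s.region for s in sites],
            "on_main_island": [s.on_main_island for s in sites],
            "area_km2": [s.area_km2 for s in sites],
        }
    ).set_index("site_id")


def write_sites(sites: Sequence[Site], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path)


def read_sites(path: str | Path) -> list[Site]:
    df = pd.read_csv(path, index_col=0)
    out = []
    for sid, row in df.iterrows():
        out.append(
            Site(
                site_id=str(sid),
                kind=str(row["kind"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                region=str(row["region"]),
                on_main_island=_to_bool(row["on_main_island"]),
                area_km2=float(row.get("area_km2", 0.0)),
            )
        )
    if len({s.site_id for s in out}) != len(out):
        raise DomainError("duplicate site ids in sites table")
    return out


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("1", "true", "yes")


def write_community(cm: CommunityMatrix, path: str | Path) -> None:
    cm.occurrence.to_csv(path)


def read_community(path: str | Path) -> CommunityMatrix:
    return CommunityMatrix(pd.read_csv(path, index_col=0))


def read_traits(path: str | Path) -> pd.DataFrame:
    """Species x trait table; non-trait columns (e.g. sample_n) pass through."""
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"trait table lacks columns: {missing}")
    if df.index.has_duplicates:
        raise DomainError("duplicate species in trait table")
    if not np.isfinite(df[list(TRAIT_COLUMNS)].to_numpy()).all():
        raise DomainError("non-finite trait values")
    return df


def average_specimens(specimens: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-specimen measurement table to species means.

    Expects a ``species`` column plus the four wing-trait columns; returns
    one row per species with the arithmetic mean of each trait and a
    ``sample_n`` count.
    """
    grouped = specimens.groupby("species")
    means = grouped[list(TRAIT_COLUMNS)].mean()
    means["sample_n"] = grouped.size()
    return means


def read_factors(env_path: str | Path, hist_path: str | Path) -> FactorSet:
    env = pd.read_csv(env_path, index_col=0)
    hist = pd.read_csv(hist_path, index_col=0)
    return FactorSet(environmental=env, historical=hist)


def write_factors(factors: FactorSet, env_path: str | Path, hist_path: str | Path) -> None:
    factors.environmental.to_csv(env_path)
    factors.historical.to_csv(hist_path)


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise DomainError("matrix row and column labels differ")
    return df


def write_square_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)
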