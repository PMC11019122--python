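import numpy as np
import pandas as pd
import pytest

from islandbeta.core_io import CommunityMatrix, Site


def make_sites(n, lat0=30.0, main_flags=None, regions=None):
    """Simple site row for geometry-light tests: a diagonal chain of grids."""
    sites = []
    for i in range(n):
        sites.append(
            Site(
                site_id=f"s{i:02d}",
                kind="grid",
                lon=133.0 + 0.31 * i,
                lat=lat0 + 0.43 * i,
                region=(regions[i] if regions else "HSK"),
                on_main_island=(main_flags[i] if main_flags else True),
                area_km2=6400.0,
            )
        )
    return sites


def random_community(rng, n_sites=12, n_species=8, p=0.5, index=None):
    occ = (rng.random((n_sites, n_species)) < p).astype(int)
    occ[occ.sum(axis=1) == 0, 0] = 1
    idx = index or [f"s{i:02d}" for i in range(n_sites)]
    return CommunityMatrix(
        pd.DataFrame(occ, index=idx, columns=[f"sp{j:02d}" for j in range(n_species)])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
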