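import numpy as np
import pandas as pd
import pytest

from trophogeo.community import CommunityTable
from trophogeo.grid import WorldGrid
from trophogeo import synth


@pytest.fixture(scope="session")
def grid():
    return WorldGrid.from_resolution(5.0)


@pytest.fixture(scope="session")
def env(grid):
    return synth.generate_environment(grid, seed=1)


@pytest.fixture(scope="session")
def biomes(env):
    return synth.generate_biomes(env)


@pytest.fixture(scope="session")
def small_dataset(env):
    """12 species, 80 sites, shallow sequencing — fast shared dataset."""
    species = synth.generate_species(
        {"mixotroph": 4, "strict_phototroph": 4, "strict_phagotroph": 4},
        env, seed=2)
    return synth.simulate_sampling(species, env, n_sites=80, depth=3000, seed=3)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return CommunityTable(counts=small_dataset.counts,
                         site_meta=small_dataset.site_meta)


def toy_table(counts: np.ndarray, depth_m=None, mld_m=None) -> CommunityTable:
    """Community table with bare-bones metadata for unit tests."""
    counts = np.asarray(counts)
    n_sp, n_si = counts.shape
    sites = [f"s{j}" for j in range(n_si)]
    meta = pd.DataFrame({
        "lat": np.zeros(n_si),
        "lon": np.zeros(n_si),
        "depth_m": np.full(n_si, 10.0) if depth_m is None else np.asarray(depth_m, float),
        "month": np.ones(n_si, dtype=int),
        "mld_m": np.full(n_si, 50.0) if mld_m is None else np.asarray(mld_m, float),
    }, index=pd.Index(sites, name="site_id"))
    df = pd.DataFrame(counts, index=pd.Index([f"sp{i}" for i in range(n_sp)], name="species_id"),
                      columns=pd.Index(sites, name="site_id"))
    return CommunityTable(counts=df, site_meta=meta)
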