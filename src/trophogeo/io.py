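"""On-disk formats: TSV count tables, CSV metadata, NetCDF3 gridded fields.

Every writer has a matching reader and round-trips its object; gridded
fields use xarray's scipy (NetCDF3) backend, which writes byte-identical
files for identical inputs — the property the pipeline manifest relies on.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .community import CommunityTable
from .grid import WorldGrid
from .sdm import HSIMap
from .synth import BiomeMask, EnvClimatology, SyntheticDataset

_ENGINE = "scipy"


# -- tabular ----------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "species_id"
    df.columns.name = "site_id"
    return df


def write_site_meta(meta: pd.DataFrame, path: Path) -> None:
    meta.to_csv(path, sep="\t")


def read_site_meta(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path: Path) -> None:
    traits.to_csv(path)


def read_traits(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_community(counts_path: Path, meta_path: Path) -> CommunityTable:
    return CommunityTable(counts=read_counts(counts_path),
                          site_meta=read_site_meta(meta_path))


# -- gridded ----------------------------------------------------------------

def _grid_coords(grid: WorldGrid) -> dict:
    return {"lat": grid.lat_centers, "lon": grid.lon_centers}


def _grid_from_ds(ds: xr.Dataset) -> WorldGrid:
    return WorldGrid(ds["lat"].values, ds["lon"].values)


def write_climatology(env: EnvClimatology, path: Path) -> None:
    ds = xr.Dataset(
        {name: (("month", "lat", "lon"), field) for name, field in env.monthly.items()},
        coords={"month": np.arange(1, 13), **_grid_coords(env.grid)},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_climatology(path: Path) -> EnvClimatology:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    grid = _grid_from_ds(ds)
    monthly = {str(name): ds[name].values for name in ds.data_vars}
    return EnvClimatology(grid=grid, monthly=monthly)


def write_biomes(biomes: BiomeMask, path: Path, vocab_path: Path) -> None:
    ds = xr.Dataset({"biome": (("lat", "lon"), biomes.labels.astype(np.int32))},
                    coords=_grid_coords(biomes.grid))
    ds.to_netcdf(path, engine=_ENGINE)
    vocab_path.write_text(json.dumps(list(biomes.vocabulary)))


def read_biomes(path: Path, vocab_path: Path) -> BiomeMask:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    vocab = tuple(json.loads(Path(vocab_path).read_text()))
    return BiomeMask(grid=_grid_from_ds(ds), labels=ds["biome"].values.astype(int),
                     vocabulary=vocab)


def write_species_grids(grids: dict[str, np.ndarray], grid: WorldGrid, path: Path) -> None:
    """Stack of per-species (lat, lon) grids, e.g. truth suitability."""
    ids = list(grids)
    data = np.stack([grids[i] for i in ids])
    ds = xr.Dataset({"value": (("species", "lat", "lon"), data)},
                    coords={"species": ids, **_grid_coords(grid)})
    ds.to_netcdf(path, engine=_ENGINE)


def read_species_grids(path: Path) -> tuple[dict[str, np.ndarray], WorldGrid]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    grid = _grid_from_ds(ds)
    out = {str(s): ds["value"].sel(species=s).values for s in ds["species"].values}
    return out, grid


def write_hsi_maps(maps: list[HSIMap], grid: WorldGrid, path: Path) -> None:
    ids = [m.species_id for m in maps]
    data = np.stack([m.monthly for m in maps]).astype(np.float32)
    ds = xr.Dataset({"hsi": (("species", "month", "lat", "lon"), data)},
                    coords={"species": ids, "month": np.arange(1, 13),
                            **_grid_coords(grid)})
    ds.to_netcdf(path, engine=_ENGINE)


def read_hsi_maps(path: Path) -> tuple[list[HSIMap], WorldGrid]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    grid = _grid_from_ds(ds)
    maps = [HSIMap(species_id=str(s), monthly=ds["hsi"].sel(species=s).values.astype(float))
            for s in ds["species"].values]
    return maps, grid


def write_dataset(dataset: SyntheticDataset, out_dir: Path) -> list[Path]:
    """Write every piece of a synthetic dataset; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    def p(name: str) -> Path:
        paths.append(out_dir / name)
        return out_dir / name

    write_counts(dataset.counts, p("community.tsv"))
    write_site_meta(dataset.site_meta, p("sites.tsv"))
    write_traits(dataset.traits, p("traits.csv"))
    write_climatology(dataset.env, p("env.nc"))
    write_biomes(dataset.biomes, p("biomes.nc"), p("biome_vocab.json"))
    write_species_grids(dataset.truth, dataset.env.grid, p("truth.nc"))
    specs = pd.DataFrame([{
        "species_id": sp.species_id,
        "trait_label": sp.trait_label,
        "max_abundance": sp.max_abundance,
        "niche": json.dumps({"centers": sp.niche_centers, "breadths": sp.niche_breadths}),
    } for sp in dataset.species]).set_index("species_id")
    specs.to_csv(p("species_specs.csv"))
    return paths
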