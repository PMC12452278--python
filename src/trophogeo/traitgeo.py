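"""Trait-level habitat-suitability aggregation and comparative statistics.

Species-level annual suitability grids are stacked by coarse trophic
strategy (the four mixotrophy classes pool into "mixotroph") into a
per-cell mean and an across-species standard deviation. The comparative
toolkit covers: latitudinal suitability profiles and their rank correlation
with absolute latitude per hemisphere, between-strategy map correlations,
biome-mean suitability with cross-strategy rank-sum tests, intra-strategy
variability (how much species within one strategy disagree, globally and
per biome), and the placement of suitability fields inside the abiotic
environmental space as supplementary PCA variables.

All spatial means are cos(latitude) area-weighted by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .envspace import GRID_PCA_VARIABLES, SupplementaryPCA
from .grid import WorldGrid, weighted_mean
from .sdm import HSIMap
from .synth import BiomeMask, EnvClimatology


@dataclass
class TraitHSIMap:
    trait_label: str
    mean_grid: np.ndarray
    sd_grid: np.ndarray | None   # None (flagged) when n_species < 2
    n_species: int
    grid: WorldGrid


@dataclass
class LatProfile:
    band_centers: np.ndarray
    zonal_mean: np.ndarray
    rho_north: float
    p_north: float
    rho_south: float
    p_south: float


def stack_trait(maps: list[HSIMap], traits: pd.Series, trait_label: str,
                grid: WorldGrid, coarse_map: dict[str, str] | None = None) -> TraitHSIMap:
    """Per-cell mean and sample SD (n-1) of member species' annual grids."""
    from .synth import COARSE_MAP
    cm = coarse_map or COARSE_MAP
    coarse = traits.map(lambda t: cm.get(t, t))
    member_grids = [m.annual for m in maps
                    if m.species_id in coarse.index and coarse[m.species_id] == trait_label]
    if not member_grids:
        raise ValueError(f"no species map with trait {trait_label!r}")
    stack = np.stack(member_grids)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(member_grids) >= 2 else None
    return TraitHSIMap(trait_label=trait_label, mean_grid=mean, sd_grid=sd,
                       n_species=len(member_grids), grid=grid)


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rho with the convention that an all-tied input gives
    (0, 1) instead of NaN."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def lat_profile(trait_map: TraitHSIMap, weights: str = "cos") -> LatProfile:
    """Zonal-mean suitability per latitude band and its Spearman correlation
    with |latitude| in each hemisphere (a band centered on the equator would
    enter both).

    The rho is signed against |latitude|: a poleward decrease gives a
    negative rho; report |rho| for a magnitude-of-decrease reading.
    """
    grid = trait_map.grid
    lats = grid.lat_centers
    if (lats > 0).sum() < 3 or (lats < 0).sum() < 3:
        raise ValueError("need at least 3 latitude bands per hemisphere")
    zonal = np.nanmean(trait_map.mean_grid, axis=1)  # weights constant per band
    north = lats >= 0
    south = lats <= 0
    rho_n, p_n = _safe_spearman(zonal[north], np.abs(lats[north]))
    rho_s, p_s = _safe_spearman(zonal[south], np.abs(lats[south]))
    return LatProfile(band_centers=lats, zonal_mean=zonal,
                      rho_north=rho_n, p_north=p_n, rho_south=rho_s, p_south=p_s)


def map_correlation(a: TraitHSIMap, b: TraitHSIMap) -> tuple[float, float]:
    """Spearman rho between two suitability maps over pairwise-finite cells."""
    if a.mean_grid.shape != b.mean_grid.shape:
        raise ValueError("grid mismatch between maps")
    x = a.mean_grid.ravel()
    y = b.mean_grid.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    return _safe_spearman(x[ok], y[ok])


def biome_stats(trait_map: TraitHSIMap, biomes: BiomeMask,
                weights: str = "cos") -> pd.DataFrame:
    """Area-weighted mean suitability and cell count per biome."""
    if biomes.labels.shape != trait_map.mean_grid.shape:
        raise ValueError("biome mask not aligned to the map grid")
    w = trait_map.grid.cell_area_weights if weights == "cos" else np.ones(trait_map.grid.shape)
    rows = []
    for code, name in enumerate(biomes.vocabulary):
        mask = biomes.labels == code
        if not mask.any():
            rows.append({"biome": name, "mean_hsi": np.nan, "n_cells": 0})
            continue
        rows.append({
            "biome": name,
            "mean_hsi": weighted_mean(trait_map.mean_grid[mask], w[mask]),
            "n_cells": int(mask.sum()),
        })
    return pd.DataFrame(rows).set_index("biome")


def biome_distributions(trait_map: TraitHSIMap, biomes: BiomeMask,
                        field: str = "mean") -> dict[str, np.ndarray]:
    grid = trait_map.mean_grid if field == "mean" else trait_map.sd_grid
    if grid is None:
        raise ValueError(f"{field} grid undefined for {trait_map.trait_label}")
    out = {}
    for code, name in enumerate(biomes.vocabulary):
        mask = biomes.labels == code
        if mask.any():
            out[name] = grid[mask]
    return out


def _pairwise_tests(dists: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum across traits, per biome, Holm-adjusted."""
    rows = []
    for biome in sorted({b for d in dists.values() for b in d}):
        traits = [t for t in dists if biome in dists[t]]
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                a, b = dists[traits[i]][biome], dists[traits[j]][biome]
                s, p = stats.ranksums(a, b)
                rows.append({"biome": biome, "trait_a": traits[i],
                             "trait_b": traits[j], "statistic": float(s),
                             "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df


def biome_trait_tests(trait_maps: dict[str, TraitHSIMap],
                      biomes: BiomeMask) -> pd.DataFrame:
    """Cross-strategy comparisons of per-biome suitability distributions."""
    dists = {t: biome_distributions(m, biomes, "mean") for t, m in trait_maps.items()}
    return _pairwise_tests(dists)


def intragroup_variability(trait_maps: dict[str, TraitHSIMap],
                           biomes: BiomeMask,
                           weights: str = "cos") -> tuple[pd.Series, pd.DataFrame]:
    """Across-species disagreement within each strategy.

    Returns the area-weighted global mean of the per-cell across-species SD
    per trait, and the Holm-adjusted pairwise rank-sum tests of the
    per-biome SD distributions across traits. Traits with fewer than two
    species carry no SD grid and are excluded with a warning.
    """
    usable = {}
    for t, m in trait_maps.items():
        if m.sd_grid is None:
            warnings.warn(f"trait {t!r} has < 2 species; excluded from variability")
            continue
        usable[t] = m
    if not usable:
        raise ValueError("no trait with >= 2 species")
    w0 = next(iter(usable.values())).grid
    w = w0.cell_area_weights if weights == "cos" else np.ones(w0.shape)
    global_sd = pd.Series({t: weighted_mean(m.sd_grid, w) for t, m in usable.items()},
                          name="mean_sd")
    dists = {t: biome_distributions(m, biomes, "sd") for t, m in usable.items()}
    return global_sd, _pairwise_tests(dists)


def hsi_env_pca(env: EnvClimatology,
                maps: dict[str, TraitHSIMap] | list[HSIMap],
                variables: tuple[str, ...] = GRID_PCA_VARIABLES) -> SupplementaryPCA:
    """PCA of the annual environmental fields over grid cells, with
    suitability grids flattened in as supplementary quantitative columns."""
    active = env.annual_matrix(list(variables))
    if isinstance(maps, dict):
        sup = {t: m.mean_grid.ravel() for t, m in maps.items()}
        shapes = {m.mean_grid.shape for m in maps.values()}
    else:
        sup = {m.species_id: m.annual.ravel() for m in maps}
        shapes = {m.annual.shape for m in maps}
    if shapes and shapes != {env.grid.shape}:
        raise ValueError("suitability grids not aligned to the climatology grid")
    return SupplementaryPCA(standardize=True).fit(active, supplementary=pd.DataFrame(sup))
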