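"""Trait-level stacking, latitudinal profiles, map correlations, biome
statistics and intra-strategy variability."""

import numpy as np
import pandas as pd
import pytest

from trophogeo.grid import WorldGrid, weighted_mean
from trophogeo.sdm import HSIMap
from trophogeo.synth import BiomeMask, BiomeRule, generate_biomes
from trophogeo.traitgeo import (
    TraitHSIMap,
    biome_stats,
    biome_trait_tests,
    hsi_env_pca,
    intragroup_variability,
    lat_profile,
    map_correlation,
    stack_trait,
)


def _map_from_grid(grid, values, species_id="sp"):
    monthly = np.broadcast_to(values, (12, *grid.shape)).copy()
    return HSIMap(species_id=species_id, monthly=monthly)


def _trait_map(grid, mean, sd=None, n=2, label="mixotroph"):
    return TraitHSIMap(trait_label=label, mean_grid=mean, sd_grid=sd,
                       n_species=n, grid=grid)


@pytest.fixture
def traits_two():
    return pd.Series({"a": "CM", "b": "pSNCM"})


class TestStackTrait:
    def test_constant_grids_mean_and_sample_sd(self, grid, traits_two):
        maps = [_map_from_grid(grid, np.full(grid.shape, 0.2), "a"),
                _map_from_grid(grid, np.full(grid.shape, 0.8), "b")]
        out = stack_trait(maps, traits_two, "mixotroph", grid)
        assert np.allclose(out.mean_grid, 0.5)
        assert np.allclose(out.sd_grid, 0.42426, atol=1e-5)

    def test_single_species_sd_flagged_undefined(self, grid):
        maps = [_map_from_grid(grid, np.full(grid.shape, 0.4), "a")]
        out = stack_trait(maps, pd.Series({"a": "CM"}), "mixotroph", grid)
        assert out.sd_grid is None and out.n_species == 1
        assert np.allclose(out.mean_grid, 0.4)

    def test_identical_species_sd_zero(self, grid, traits_two):
        maps = [_map_from_grid(grid, np.full(grid.shape, 0.6), s) for s in "ab"]
        out = stack_trait(maps, traits_two, "mixotroph", grid)
        assert np.allclose(out.sd_grid, 0.0)

    def test_missing_trait_rejected(self, grid, traits_two):
        maps = [_map_from_grid(grid, np.zeros(grid.shape), "a")]
        with pytest.raises(ValueError, match="strict_phagotroph"):
            stack_trait(maps, traits_two, "strict_phagotroph", grid)


class TestLatProfile:
    def test_poleward_decrease_gives_rho_minus_one(self, grid):
        hsi = np.cos(np.deg2rad(grid.lat_grid))  # strictly decreasing poleward
        lp = lat_profile(_trait_map(grid, hsi))
        assert lp.rho_north == pytest.approx(-1.0)
        assert lp.rho_south == pytest.approx(-1.0)

    def test_flat_profile_rho_zero(self, grid):
        lp = lat_profile(_trait_map(grid, np.full(grid.shape, 0.5)))
        assert lp.rho_north == 0.0 and lp.p_north == 1.0
        assert lp.rho_south == 0.0

    def test_warm_water_trait_strongly_latitudinal(self, env, grid):
        # a warm-optimum suitability field correlates strongly with |lat|
        hsi = np.exp(-((env.annual("SST") - 27.0) ** 2) / 50.0)
        lp = lat_profile(_trait_map(grid, hsi))
        assert abs(lp.rho_north) >= 0.8
        assert abs(lp.rho_south) >= 0.8


class TestMapCorrelation:
    def test_self_correlation_one(self, grid):
        rng = np.random.default_rng(0)
        m = _trait_map(grid, rng.uniform(size=grid.shape))
        rho, _ = map_correlation(m, m)
        assert rho == pytest.approx(1.0)

    def test_complement_correlation_minus_one(self, grid):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=grid.shape)
        rho, _ = map_correlation(_trait_map(grid, vals), _trait_map(grid, 1 - vals))
        assert rho == pytest.approx(-1.0)

    def test_independent_noise_maps_near_zero(self):
        big = WorldGrid(np.linspace(-88, 88, 100), np.linspace(-179, 179, 100))
        rng = np.random.default_rng(2)
        a = _trait_map(big, rng.uniform(size=big.shape))
        b = _trait_map(big, rng.uniform(size=big.shape))
        rho, _ = map_correlation(a, b)
        assert abs(rho) < 0.03

    def test_monotone_transform_invariance(self, grid):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=grid.shape)
        other = rng.uniform(size=grid.shape)
        r1, _ = map_correlation(_trait_map(grid, vals), _trait_map(grid, other))
        r2, _ = map_correlation(_trait_map(grid, vals ** 3), _trait_map(grid, other))
        assert r1 == pytest.approx(r2)

    def test_grid_mismatch_rejected(self, grid):
        small = WorldGrid(np.linspace(-60, 60, 5), np.linspace(-150, 150, 6))
        with pytest.raises(ValueError, match="mismatch"):
            map_correlation(_trait_map(grid, np.zeros(grid.shape)),
                            _trait_map(small, np.zeros(small.shape)))


class TestBiomeStats:
    def test_constant_map_every_biome_mean_equal(self, grid, biomes):
        out = biome_stats(_trait_map(grid, np.full(grid.shape, 0.6)), biomes)
        assert np.allclose(out["mean_hsi"].dropna(), 0.6)

    def test_biome_means_bracketed_by_cell_extremes(self, grid, biomes):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=grid.shape)
        out = biome_stats(_trait_map(grid, vals), biomes)
        means = out["mean_hsi"].dropna()
        assert (means >= vals.min() - 1e-12).all()
        assert (means <= vals.max() + 1e-12).all()

    def test_disjoint_high_regions_max_in_own_biome(self, grid, env):
        # two traits peaking in cold vs warm water find their maxima in the
        # corresponding SST-defined biomes
        rules = [BiomeRule("cold", sst=(-np.inf, 10.0)),
                 BiomeRule("warm", sst=(10.0, np.inf))]
        mask = generate_biomes(env, rules)
        sst = env.annual("SST")
        cold_trait = _trait_map(grid, (sst < 10).astype(float))
        warm_trait = _trait_map(grid, (sst >= 10).astype(float))
        assert biome_stats(cold_trait, mask)["mean_hsi"].idxmax() == "cold"
        assert biome_stats(warm_trait, mask)["mean_hsi"].idxmax() == "warm"

    def test_identical_trait_maps_tests_not_significant(self, grid, biomes):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=grid.shape)
        maps = {"mixotroph": _trait_map(grid, vals),
                "strict_phagotroph": _trait_map(grid, vals.copy(),
                                                label="strict_phagotroph")}
        tests = biome_trait_tests(maps, biomes)
        assert (tests["p_value"] > 0.95).all()

    def test_empty_biome_reported_missing_not_error(self, grid):
        labels = np.zeros(grid.shape, dtype=int)   # second biome never used
        mask = BiomeMask(grid=grid, labels=labels, vocabulary=("only", "never"))
        out = biome_stats(_trait_map(grid, np.full(grid.shape, 0.3)), mask)
        assert np.isnan(out.loc["never", "mean_hsi"])
        assert out.loc["never", "n_cells"] == 0


class TestIntragroupVariability:
    def test_identical_species_give_zero_sd(self, grid, biomes):
        maps = {"mixotroph": _trait_map(grid, np.full(grid.shape, 0.5),
                                        sd=np.zeros(grid.shape))}
        global_sd, _ = intragroup_variability(maps, biomes)
        assert global_sd["mixotroph"] == 0.0

    def test_constant_sd_recovered_exactly(self, grid, biomes):
        maps = {"mixotroph": _trait_map(grid, np.full(grid.shape, 0.5),
                                        sd=np.full(grid.shape, 0.42426))}
        global_sd, _ = intragroup_variability(maps, biomes)
        assert global_sd["mixotroph"] == pytest.approx(0.42426)

    def test_trait_without_sd_excluded_with_warning(self, grid, biomes):
        maps = {"mixotroph": _trait_map(grid, np.full(grid.shape, 0.5),
                                        sd=np.zeros(grid.shape)),
                "strict_phototroph": _trait_map(grid, np.zeros(grid.shape),
                                                sd=None, n=1,
                                                label="strict_phototroph")}
        with pytest.warns(UserWarning, match="excluded"):
            global_sd, _ = intragroup_variability(maps, biomes)
        assert list(global_sd.index) == ["mixotroph"]

    def test_divergent_group_has_larger_sd_than_concordant(self, grid, biomes):
        rng = np.random.default_rng(0)
        base = rng.uniform(size=grid.shape)
        maps = {
            "mixotroph": _trait_map(grid, base, sd=np.full(grid.shape, 0.05)),
            "strict_phagotroph": _trait_map(grid, base,
                                            sd=np.full(grid.shape, 0.4),
                                            label="strict_phagotroph"),
        }
        global_sd, tests = intragroup_variability(maps, biomes)
        assert global_sd["strict_phagotroph"] > global_sd["mixotroph"]
        assert (tests["p_holm"] < 0.01).all()


class TestAreaWeighting:
    def test_weighted_mean_of_constant_is_constant(self, grid):
        vals = np.full(grid.shape, 0.73)
        assert weighted_mean(vals, grid.cell_area_weights) == pytest.approx(0.73, abs=1e-12)

    def test_tropics_dominate_cosine_weighting(self, grid):
        vals = np.where(np.abs(grid.lat_grid) < 30, 1.0, 0.0)
        wm = weighted_mean(vals, grid.cell_area_weights)
        assert wm > vals.mean()   # tropical cells carry more area


class TestHsiEnvPCA:
    def test_sst_copy_supplementary_matches_sst_correlations(self, env, grid):
        sup = {"sstcopy": _trait_map(grid, env.annual("SST"))}
        res = hsi_env_pca(env, sup)
        # correlation of the supplementary copy with PC scores equals the
        # correlation of the active SST column with the same scores
        scores = res.scores_
        sst = env.annual("SST").ravel()
        for c in range(2):
            expected = np.corrcoef(sst, scores[:, c])[0, 1]
            got = res.supplementary_correlations_.loc["sstcopy", f"PC{c+1}"]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_warm_water_trait_anticorrelates_with_cold_nutrient_pole(self, env, grid):
        hsi = np.exp(-((env.annual("SST") - 27.0) ** 2) / 50.0)
        res = hsi_env_pca(env, {"mixo": _trait_map(grid, hsi)})
        pc1 = res.supplementary_correlations_.loc["mixo", "PC1"]
        no3_loading = res.loadings_.loc["NO3", "PC1"]
        # the warm-water trait sits opposite the nutrient-rich/cold pole
        assert np.sign(pc1) == -np.sign(no3_loading)
        assert abs(pc1) > 0.7

    def test_constant_supplementary_flagged(self, env, grid):
        res = hsi_env_pca(env, {"flat": _trait_map(grid, np.full(grid.shape, 0.5))})
        assert "flat" in res.supplementary_degenerate_
        assert (res.supplementary_correlations_.loc["flat"] == 0).all()

    def test_grid_mismatch_rejected(self, env):
        small = WorldGrid(np.linspace(-60, 60, 5), np.linspace(-150, 150, 6))
        bad = {"x": _trait_map(small, np.zeros(small.shape))}
        with pytest.raises(ValueError, match="aligned"):
            hsi_env_pca(env, bad)
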