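"""End-to-end pipeline: simulate -> community -> envspace -> ordination ->
sdm -> traitmaps, with strict configuration, per-stage seeds fanned out from
one global seed, and a content-hash manifest for reproducibility checks.

Each stage reads its inputs from the output directory, so any stage can be
re-run independently given the prior stages' files on disk (or user-supplied
files in the same formats).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import community as comm
from . import envspace as esp
from . import io as tio
from . import ordination as ord_
from . import sdm as sdm_
from . import synth
from . import traitgeo as tg
from .grid import WorldGrid
from .sdm import derive_seed

log = logging.getLogger("trophogeo")

STAGES = ("simulate", "community", "envspace", "ordination", "sdm", "traitmaps")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    resolution: float = 5.0
    n_sites: int = 300
    depth: int = 10_000
    n_per_trait: dict[str, int] = Field(
        default_factory=lambda: {t: 20 for t in synth.COARSE_TRAITS})


class CommunityConfig(_Strict):
    min_reads: int = 100
    euphotic_max_depth: float = 200.0
    k_categories: int = 3


class EnvspaceConfig(_Strict):
    k: int = 4
    variance_threshold: float = 0.8
    variables: list[str] = Field(default_factory=lambda: list(esp.SITE_PCA_VARIABLES))


class OrdinationConfig(_Strict):
    rv_threshold: float = 0.9
    max_k: int = 90
    selection: str = "backward"   # backward | forward | none


class SdmConfig(_Strict):
    families: list[str] = Field(default_factory=lambda: ["GLM", "GAM", "MARS", "ANN"])
    reps: int = 5
    split: float = 0.2
    retention: float = 0.3
    min_occ: int = 20
    top_predictors: int = 4
    candidate_predictors: list[str] = Field(
        default_factory=lambda: list(esp.GRID_PCA_VARIABLES))


class TraitmapsConfig(_Strict):
    weights: str = "cos"


class PipelineConfig(_Strict):
    seed: int = 1
    out_dir: str = "pipeline_out"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    community: CommunityConfig = Field(default_factory=CommunityConfig)
    envspace: EnvspaceConfig = Field(default_factory=EnvspaceConfig)
    ordination: OrdinationConfig = Field(default_factory=OrdinationConfig)
    sdm: SdmConfig = Field(default_factory=SdmConfig)
    traitmaps: TraitmapsConfig = Field(default_factory=TraitmapsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = derive_seed(cfg.seed, "simulate")
    grid = WorldGrid.from_resolution(cfg.simulate.resolution)
    env = synth.generate_environment(grid, seed=seed)
    species = synth.generate_species(cfg.simulate.n_per_trait, env,
                                     seed=derive_seed(seed, "species"))
    ds = synth.simulate_sampling(species, env, n_sites=cfg.simulate.n_sites,
                                 depth=cfg.simulate.depth,
                                 seed=derive_seed(seed, "sampling"))
    return tio.write_dataset(ds, out)


def _load_community(out: Path) -> comm.CommunityTable:
    return tio.read_community(out / "community.tsv", out / "sites.tsv")


def stage_community(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = _load_community(out)
    traits = comm.TraitTable(tio.read_traits(out / "traits.csv"))
    filtered = comm.filter_community(table, min_reads=cfg.community.min_reads,
                                     euphotic_max_depth=cfg.community.euphotic_max_depth)
    metrics = comm.species_metrics(filtered)
    metrics = comm.classify_ubiquity(metrics, k=cfg.community.k_categories)
    metrics["trait_label"] = traits.labels.reindex(metrics.index)
    tests = []
    for var in ("occupancy", "evenness"):
        h, p = comm.trait_group_test(metrics, traits, variable=var)
        tests.append({"variable": var, "H": h, "p_value": p})
    paths = [out / "species_metrics.csv", out / "trait_tests.csv",
             out / "filtered_sites.txt"]
    metrics.to_csv(paths[0])
    pd.DataFrame(tests).to_csv(paths[1], index=False)
    paths[2].write_text("\n".join(filtered.counts.columns) + "\n")
    return paths


def _site_env_matrix(out: Path, variables: list[str],
                     monthly_matched: bool = False) -> pd.DataFrame:
    env = tio.read_climatology(out / "env.nc")
    meta = tio.read_site_meta(out / "sites.tsv")
    cells = meta["cell"].to_numpy(dtype=int)
    months = meta["month"].to_numpy(dtype=int) if monthly_matched else None
    X = env.at_cells(list(variables), cells, months)
    X.index = meta.index
    return X


def _filtered_site_ids(out: Path) -> list[str]:
    f = out / "filtered_sites.txt"
    if f.exists():
        return [s for s in f.read_text().splitlines() if s]
    return list(tio.read_site_meta(out / "sites.tsv").index)


def stage_envspace(cfg: PipelineConfig, out: Path) -> list[Path]:
    sites = _filtered_site_ids(out)
    X = _site_env_matrix(out, cfg.envspace.variables).loc[sites]
    result = esp.pca(X)
    clusters = esp.HCPC(k=cfg.envspace.k,
                        variance_threshold=cfg.envspace.variance_threshold).fit(result)
    paths = [out / "pca_loadings.csv", out / "pca_scores.csv", out / "site_clusters.csv"]
    result.loadings_.to_csv(paths[0])
    pd.DataFrame(result.scores_, index=X.index,
                 columns=[f"PC{i+1}" for i in range(result.scores_.shape[1])]).to_csv(paths[1])
    pd.DataFrame({"cluster": clusters.labels_}, index=X.index).to_csv(paths[2])
    return paths


def stage_ordination(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = _load_community(out)
    sites = _filtered_site_ids(out)
    table = comm.CommunityTable(counts=table.counts[sites],
                                site_meta=table.site_meta.loc[sites])
    hell = comm.relative_hellinger(table)            # sites x species
    sel = ord_.escoufier_select(hell, threshold=cfg.ordination.rv_threshold,
                                max_k=cfg.ordination.max_k)
    Y = hell[sel.ordered_selected_ids]
    X = _site_env_matrix(out, list(esp.SITE_PCA_VARIABLES)).loc[sites]
    if cfg.ordination.selection in ("backward", "forward"):
        names, trace = ord_.aic_backward_select(Y, X, direction=cfg.ordination.selection)
        if not names:
            names = list(X.columns)
    else:
        names, trace = list(X.columns), []
    rda = ord_.rda_fit(Y, X[names])
    paths = [out / "escoufier_trace.csv", out / "aic_trace.csv",
             out / "rda_sites.csv", out / "rda_species.csv",
             out / "rda_biplot.csv", out / "rda_summary.json"]
    pd.DataFrame({"species_id": sel.ordered_selected_ids,
                  "rv": sel.rv_trajectory}).to_csv(paths[0], index=False)
    pd.DataFrame(trace, columns=["action", "aic"]).to_csv(paths[1], index=False)
    axes = [f"RDA{i+1}" for i in range(rda.site_scores_.shape[1])]
    pd.DataFrame(rda.site_scores_, index=Y.index, columns=axes).to_csv(paths[2])
    rda.species_scores_.to_csv(paths[3])
    rda.biplot_scores_.to_csv(paths[4])
    paths[5].write_text(json.dumps({
        "predictors": names,
        "r_squared": rda.r_squared_,
        "adjusted_r_squared": rda.adjusted_r_squared_,
        "proportion_explained": list(map(float, rda.proportion_explained_)),
        "axes12_percent": float(100 * rda.proportion_explained_[:2].sum()),
    }, indent=1))
    return paths


def stage_sdm(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = _load_community(out)
    sites = _filtered_site_ids(out)
    table = comm.CommunityTable(counts=table.counts[sites],
                                site_meta=table.site_meta.loc[sites])
    env = tio.read_climatology(out / "env.nc")
    predictors = _site_env_matrix(out, cfg.sdm.candidate_predictors,
                                  monthly_matched=True).loc[sites]
    seed = derive_seed(cfg.seed, "sdm")
    specs, maps, skipped = [], [], []
    for sp_id in table.counts.index:
        pa = sdm_.build_pa(table, sp_id, predictors, min_occurrences=cfg.sdm.min_occ)
        if isinstance(pa, sdm_.SkipMarker):
            skipped.append({"species_id": sp_id, "reason": pa.reason})
            continue
        names = sdm_.select_predictors(pa, top_k=cfg.sdm.top_predictors,
                                       seed=derive_seed(seed, sp_id, "screen"))
        pa.predictors = pa.predictors[names]
        try:
            spec, _ = sdm_.cross_validate(pa, families=tuple(cfg.sdm.families),
                                          n_reps=cfg.sdm.reps, split=cfg.sdm.split,
                                          retention_cutoff=cfg.sdm.retention,
                                          seed=derive_seed(seed, sp_id))
        except ValueError as exc:
            skipped.append({"species_id": sp_id, "reason": str(exc)})
            continue
        specs.append(spec)
        if spec.n_retained > 0:
            maps.append(sdm_.project(spec, env))
        else:
            skipped.append({"species_id": sp_id, "reason": "no member retained"})
    if not maps:
        raise RuntimeError("no species ensemble was retained")
    paths = [out / "ensemble_manifest.csv", out / "sdm_skipped.csv", out / "hsi.nc"]
    sdm_.ensemble_manifest(specs).to_csv(paths[0], index=False)
    pd.DataFrame(skipped, columns=["species_id", "reason"]).to_csv(paths[1], index=False)
    tio.write_hsi_maps(maps, env.grid, paths[2])
    return paths


def stage_traitmaps(cfg: PipelineConfig, out: Path) -> list[Path]:
    env = tio.read_climatology(out / "env.nc")
    biomes = tio.read_biomes(out / "biomes.nc", out / "biome_vocab.json")
    maps, grid = tio.read_hsi_maps(out / "hsi.nc")
    traits = comm.TraitTable(tio.read_traits(out / "traits.csv"))
    coarse_present = sorted({synth.COARSE_MAP[traits.labels[m.species_id]]
                             for m in maps if m.species_id in traits.labels.index})
    coarse_present = [t for t in coarse_present if t != "unannotated"]
    trait_maps = {t: tg.stack_trait(maps, traits.labels, t, grid) for t in coarse_present}

    summary: dict = {"n_species": {t: m.n_species for t, m in trait_maps.items()}}
    summary["lat_profiles"] = {}
    for t, m in trait_maps.items():
        lp = tg.lat_profile(m, weights=cfg.traitmaps.weights)
        summary["lat_profiles"][t] = {
            "rho_north": lp.rho_north, "p_north": lp.p_north,
            "rho_south": lp.rho_south, "p_south": lp.p_south,
            "abs_rho_north": abs(lp.rho_north), "abs_rho_south": abs(lp.rho_south),
        }
    summary["map_correlations"] = {}
    keys = list(trait_maps)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            rho, p = tg.map_correlation(trait_maps[keys[i]], trait_maps[keys[j]])
            summary["map_correlations"][f"{keys[i]}|{keys[j]}"] = {"rho": rho, "p": p}
    summary["biome_means"] = {
        t: tg.biome_stats(m, biomes, weights=cfg.traitmaps.weights)["mean_hsi"].to_dict()
        for t, m in trait_maps.items()}
    sd_ok = {t: m for t, m in trait_maps.items() if m.sd_grid is not None}
    if len(sd_ok) >= 1:
        global_sd, sd_tests = tg.intragroup_variability(sd_ok, biomes,
                                                        weights=cfg.traitmaps.weights)
        summary["intragroup_sd"] = global_sd.to_dict()
    else:
        sd_tests = pd.DataFrame()
        summary["intragroup_sd"] = {}
    pca_res = tg.hsi_env_pca(env, trait_maps)
    summary["hsi_pca_correlations"] = {
        t: pca_res.supplementary_correlations_.loc[t, ["PC1", "PC2"]].to_dict()
        for t in trait_maps if t in pca_res.supplementary_correlations_.index}

    # reconstruction check against generator truth when available
    truth_path = out / "truth.nc"
    if truth_path.exists():
        truth, _ = tio.read_species_grids(truth_path)
        coarse = traits.coarse
        summary["trait_truth_spearman"] = {}
        for t, m in trait_maps.items():
            members = [truth[s] for s in truth if coarse.get(s) == t]
            if members:
                tgrid = np.mean(members, axis=0)
                from scipy import stats as _st
                rho, _ = _st.spearmanr(m.mean_grid.ravel(), tgrid.ravel())
                summary["trait_truth_spearman"][t] = float(rho)

    paths = [out / "trait_hsi.nc", out / "trait_summary.json",
             out / "biome_trait_tests.csv", out / "intragroup_sd_tests.csv"]
    mean_grids = {t: m.mean_grid for t, m in trait_maps.items()}
    tio.write_species_grids(mean_grids, grid, paths[0])
    paths[1].write_text(json.dumps(summary, indent=1, sort_keys=True))
    tg.biome_trait_tests(trait_maps, biomes).to_csv(paths[2], index=False)
    sd_tests.to_csv(paths[3], index=False)
    return paths


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "community": stage_community,
    "envspace": stage_envspace,
    "ordination": stage_ordination,
    "sdm": stage_sdm,
    "traitmaps": stage_traitmaps,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict[str, str]:
    """Run the requested stages in order; returns {relative path: sha256}.

    A stage failure halts the run with the failing stage named; files from
    completed stages are kept. The manifest is also written to
    ``manifest.json`` in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.monotonic()
        log.info("stage %s: start", stage)
        try:
            produced += _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        log.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)
    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(set(produced))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
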