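"""Community-table filtering, normalisation and per-species ubiquity metrics.

The observational object is a species x sites read-count table with per-site
metadata (position, sampling depth, month, climatological mixed layer
depth). Species are summarised by occupancy (number of occupied sites),
total read abundance and Pielou's evenness of their read distribution across
occupied sites, then classified into ubiquity categories by Ward clustering,
and metric distributions are compared across trophic strategies with a
Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .synth import COARSE_MAP, TRAIT_VOCABULARY

REQUIRED_SITE_COLUMNS = ("lat", "lon", "depth_m", "month", "mld_m")

UBIQUITY_CATEGORIES = ("ubiquitous", "intermediate", "rare")


@dataclass
class CommunityTable:
    """Species x sites read counts plus per-site metadata."""

    counts: pd.DataFrame     # index = species_id, columns = site_id
    site_meta: pd.DataFrame  # index = site_id

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValueError("species and site ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = set(self.counts.columns) - set(self.site_meta.index)
        if missing:
            raise ValueError(f"sites without metadata: {sorted(missing)[:5]}")
        meta = self.site_meta.loc[list(self.counts.columns)]
        for col in ("lat", "lon"):
            if col in meta and not np.isfinite(meta[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite site {col}")
        self.site_meta = self.site_meta.loc[list(self.counts.columns)]

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]


class TraitTable:
    """species_id -> trophic-strategy label from the closed 7-class
    vocabulary, with the derived coarse mapping pooling the four mixotrophy
    classes."""

    def __init__(self, labels: pd.Series | pd.DataFrame):
        if isinstance(labels, pd.DataFrame):
            labels = labels["trait_label"]
        labels = labels.astype(str)
        bad = set(labels) - set(TRAIT_VOCABULARY)
        if bad:
            raise ValueError(f"labels outside the trophic vocabulary: {sorted(bad)}")
        if not labels.index.is_unique:
            raise ValueError("duplicate species in trait table")
        self.labels = labels

    @property
    def coarse(self) -> pd.Series:
        return self.labels.map(COARSE_MAP)

    def __len__(self) -> int:
        return len(self.labels)


class EmptyResultError(ValueError):
    """All species or all sites were removed by a filter."""


def filter_community(table: CommunityTable,
                     min_reads: int = 100,
                     genus_assigned: pd.Series | None = None,
                     euphotic_max_depth: float = 200.0) -> CommunityTable:
    """Apply the standard inclusion rules.

    Species are dropped when their global read total (over the input table)
    is below ``min_reads`` — the boundary is inclusive, a species with
    exactly ``min_reads`` reads survives — or when they are not assigned at
    genus level. Sites are dropped when sampled below the climatological
    mixed layer (depth_m > mld_m) or below the euphotic cut-off. Survivor
    order is preserved.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if genus_assigned is None:
        genus_assigned = pd.Series(True, index=table.counts.index)
    missing = set(table.counts.index) - set(genus_assigned.index)
    if missing:
        raise ValueError(f"genus_assigned flags missing for: {sorted(missing)[:5]}")

    totals = table.counts.sum(axis=1)
    keep_species = (totals >= min_reads) & genus_assigned.reindex(table.counts.index).astype(bool)
    meta = table.site_meta
    keep_sites = (meta["depth_m"] <= meta["mld_m"]) & (meta["depth_m"] <= euphotic_max_depth)
    if not keep_species.any():
        raise EmptyResultError("all species removed by the filters")
    if not keep_sites.any():
        raise EmptyResultError("all sites removed by the filters")
    counts = table.counts.loc[keep_species, keep_sites[keep_sites].index]
    return CommunityTable(counts=counts, site_meta=meta.loc[counts.columns])


def relative_hellinger(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger-transformed relative abundances, samples as rows.

    entry_ij = sqrt(count_ij / total reads of sample i); each sample row has
    unit Euclidean norm.
    """
    counts = table.counts if isinstance(table, CommunityTable) else table
    samples = counts.T  # sites x species
    totals = samples.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)[:5]}")
    return np.sqrt(samples.div(totals, axis=0))


def species_metrics(table: CommunityTable) -> pd.DataFrame:
    """Occupancy, total abundance and Pielou evenness per species.

    Evenness J = H'/ln(S_occ) with H' the Shannon entropy of the read shares
    over occupied sites. Single-site species have undefined J (ln 1 = 0);
    the convention here is J = 1.0 with ``degenerate_evenness`` flagged so
    callers can exclude them.
    """
    counts = table.counts.to_numpy(dtype=float)
    occupancy = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    evenness = np.ones(len(counts))
    degenerate = occupancy <= 1
    for i in np.where(~degenerate)[0]:
        c = counts[i, counts[i] > 0]
        p = c / c.sum()
        h = -(p * np.log(p)).sum()
        evenness[i] = h / np.log(len(c))
    return pd.DataFrame({
        "occupancy": occupancy.astype(int),
        "total_abundance": total,
        "evenness": evenness,
        "degenerate_evenness": degenerate,
    }, index=table.counts.index)


class UbiquityClassifier(BaseEstimator, ClusterMixin):
    """Ward clustering of species on z-scored (occupancy, evenness).

    Clusters are mapped to ubiquity categories by mean-occupancy rank: the
    highest-occupancy cluster is "ubiquitous", the lowest "rare", everything
    else "intermediate". Standardisation makes the partition invariant to
    affine rescaling of either metric.

    Parameters
    ----------
    k : number of clusters, >= 2 (default 3).
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X, y=None):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_species, 2): occupancy, evenness")
        if X.shape[0] < self.k:
            raise ValueError(f"need at least k={self.k} species, got {X.shape[0]}")
        sd = X.std(axis=0, ddof=0)
        self.degenerate_ = bool(np.all(sd == 0))
        if self.degenerate_:
            # all species identical: a single effective cluster
            warnings.warn("degenerate partition: all species have identical metrics")
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            self.categories_ = np.array(["intermediate"] * X.shape[0])
            return self
        Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        self.linkage_ = linkage(Z, method="ward")
        raw = fcluster(self.linkage_, t=self.k, criterion="maxclust")
        order = (pd.Series(X[:, 0]).groupby(raw).mean().sort_values(ascending=False))
        cat = {}
        ids = list(order.index)
        cat[ids[0]] = "ubiquitous"
        cat[ids[-1]] = "rare"
        for c in ids[1:-1]:
            cat[c] = "intermediate"
        self.labels_ = raw
        self.categories_ = np.array([cat[c] for c in raw])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def classify_ubiquity(metrics: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Attach a ``category`` column to the metrics frame."""
    clf = UbiquityClassifier(k=k).fit(metrics[["occupancy", "evenness"]].to_numpy())
    out = metrics.copy()
    out["category"] = clf.categories_
    return out


def trait_group_test(metrics: pd.DataFrame,
                     traits: TraitTable,
                     variable: str = "occupancy",
                     exclude_degenerate: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis H and p for ``variable`` across coarse trait groups.

    Unannotated species are excluded. Groups with identical values across
    the board yield (H=0, p=1).
    """
    if variable not in metrics.columns:
        raise KeyError(f"unknown metric {variable!r}")
    coarse = traits.coarse.reindex(metrics.index)
    mask = coarse.notna() & (coarse != "unannotated")
    if exclude_degenerate and "degenerate_evenness" in metrics:
        mask &= ~metrics["degenerate_evenness"]
    values = metrics.loc[mask, variable]
    groups = [g.to_numpy(dtype=float) for _, g in values.groupby(coarse[mask])]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two trait groups with members")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
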