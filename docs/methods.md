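# Methods

This note documents the models and procedures implemented in `trophogeo`,
the design of the synthetic world they are validated against, and the
numerical choices that a user changing defaults should know about.

## Scientific setting

Marine dinoflagellates (and protists generally) span a spectrum of trophic
strategies: constitutive and non-constitutive mixotrophs (CM, GNCM, pSNCM,
eSNCM — pooled here as the coarse "mixotroph" strategy), strict phototrophs
and strict phagotrophs. Theory predicts generalist mixotrophs are favoured
in warm oligotrophic water and specialists in productive, nutrient-rich
regions. The pipeline tests whether such trait-level structure is (a)
visible in raw community metrics and (b) recoverable by stacking
per-species habitat-suitability models.

## Community metrics

Input is a species × sites read-count matrix with site metadata. Filters:
species with a global read total below `min_reads` (default 100; the
boundary is inclusive) or without genus-level assignment are dropped;
sites sampled below the climatological mixed layer (depth_m > mld_m) or
below the euphotic cut-off (default 200 m — configurable, as the criterion
itself has no canonical depth) are dropped. Species totals are evaluated on
the input table, before site removal, so a species' inclusion does not
depend on which of its sites survive.

Per species: occupancy, total abundance, and Pielou's evenness
J = H′/ln S over occupied sites only. Including structural zeros would
force J → 0 for any sparse species and destroy the contrast between "rare
but locally dominant" and "evenly spread"; occupied-sites evenness keeps
the two metrics complementary. For occupancy 1, ln S = 0 leaves J
undefined; the convention is J = 1.0 with a `degenerate_evenness` flag, so
single-site species plot at the even end but can be excluded from group
tests (`exclude_degenerate=True`).

Ubiquity categories come from Ward clustering on z-scored
(occupancy, evenness) — the standardisation makes the partition invariant
to affine rescaling of either metric. Clusters map to labels by mean
occupancy rank (highest → ubiquitous, lowest → rare, rest intermediate).
An all-identical input yields a single effective cluster and is flagged as
a degenerate partition rather than an error. Cross-strategy comparisons use
Kruskal–Wallis on coarse labels, excluding unannotated species; an
all-tied input returns (H = 0, p = 1).

## Environmental space

Thirteen variables: SST, SSS, MLD, PAR, O2, PIC, Chla, NO3, PO4, Si, NPP
plus the derived excess indices N\* = NO₃ − 16·PO₄ (nitrate excess over the
Redfield expectation) and Si\* = Si − NO₃. The indices are always
recomputed from their parents — in the generator as much as in the
site-level helper — so the defining identities hold to machine precision.

The site-level PCA uses the 11-variable set (all but PIC and NPP, which
are reserved for the grid-cell analyses); the grid-cell PCA uses all 13.
PCA is the SVD of the centered (and by default unit-variance) matrix.
Supplementary quantitative columns are correlated with the scores after
the fit and cannot influence the decomposition; a constant supplementary
column gets correlation 0 and is flagged. Sign convention: every component
is oriented so its largest-magnitude loading is positive, making outputs
reproducible across BLAS implementations.

HCPC clusters the leading scores with Ward linkage. The number of score
columns defaults to the smallest number of components reaching 80%
cumulative variance; k is a fixed configuration choice (default 4), with
the inertia-loss heuristic deliberately left to the user rather than
hidden behind a default.

## Constrained ordination

The response is the Hellinger-transformed table (samples as rows,
y_ij = √(n_ij/n_i·), unit row norms), the predictors are the standardized
11-variable annual matrix.

RDA: column-center Y, regress on X, Ŷ = X(XᵀX)⁻¹XᵀY; canonical axes are
the principal components of Ŷ, residual axes those of Y − Ŷ. Eigenvalues
are SS/(n−1); canonical plus residual eigenvalues equal the total variance
of centered Y (conserved to 1e-8 in tests). R² = SS(Ŷ)/SS(Y) with the
small-sample adjustment 1 − (1−R²)(n−1)/(n−m−1). A rank-deficient XᵀX
raises a collinearity error advising predictor screening rather than
silently pseudo-inverting.

Species selection uses Escoufier's equivalent vectors: a subset of
response columns is scored by the RV coefficient between the centered
table and its orthogonal projection onto the span of the subset, and
columns are added greedily (ties by column order) until the score reaches
the similarity threshold (default 0.90) or `max_k`. Under this
formulation a duplicated column adds exactly zero, the trajectory is
non-decreasing, and the score reaches 1 exactly when the selection spans
the table — properties the plain submatrix RV(Y_sel, Y) does not have (a
duplicated high-variance column can raise it more than an independent
column does).

Predictor selection is backward stepwise under
AIC = n·ln(RSS/n) + 2(m+1), with RSS the total multivariate residual sum
of squares — the convention of standard constrained-ordination step
selection. Forward search is available via configuration.

## Species distribution models

Presences are sites with ≥ 1 read; absences are all other sampled sites
(true absences — the sampling observed the whole community there, so no
pseudo-absence scheme is used). Species with fewer than 20 presences, or
none missing, are skipped as unmodelable.

Predictor sets are species-specific: a preliminary quadratic logistic
model supplies permutation importances (1 − correlation between
predictions before and after permuting one column, mean of 5 seeded
permutations); pairs with |Spearman ρ| > 0.7 are resolved by dropping the
less important member, visiting pairs by descending |ρ|; survivors are
ranked by importance and the top 4 kept.

Four families, each deliberately small to limit overfitting:

- **GLM** — logistic regression on linear + squared terms, near-unpenalised
  (L2 with C = 10³, which keeps perfectly separable calibration splits
  finite without visibly biasing coefficients; recovery of a known
  logistic slope at n = 2000 is within 15%).
- **GAM** — per-predictor cubic B-spline basis (5 knots) with an L2
  penalised logistic fit as the smoother.
- **MARS** — forward growth of reflected hinge pairs max(0, ±(x − t)) with
  knots at training quantiles, least-squares scored, to ≤ 9 terms; backward
  pruning by GCV with penalty 3; a logistic fit on the pruned basis yields
  probabilities.
- **ANN** — single hidden layer of 6 units (≤ 8), weight decay 10⁻²,
  L-BFGS, seeded initialisation.

Cross-validation: 5 stratified random 80/20 calibration/validation splits.
Each member picks the presence threshold maximising the Jaccard index on
its *calibration* split over the grid 0.01…0.99 (step 0.01, ties toward
the lower threshold — bit-reproducible and fine enough for the flat
Jaccard plateaus these data produce); the member's score is the Jaccard of
that thresholded prediction on the held-out split, and members with
validation Jaccard > 0.3 are retained. Every stochastic step derives its
seed from a global seed by SHA-256 hashing of (seed, species, family,
repetition), so runs are exactly repeatable.

Projection: per retained member and month, predict a probability per grid
cell and binarise at the member's threshold; the species' monthly HSI is
the fraction of members voting presence (so a committee of one produces a
binary map, and duplicating a member changes nothing); the annual map is
the monthly mean. Trait maps are unweighted per-cell means over member
species, with the across-species sample SD (n−1) as the intra-strategy
disagreement field (undefined and flagged for single-species strategies).

All spatial means are cos(latitude) area-weighted. Latitudinal profiles
correlate zonal-mean HSI with |latitude| per hemisphere (a band centered
on the equator would enter both), so a poleward decrease gives negative ρ;
reports carry |ρ| alongside for the magnitude-of-decrease reading, and a
flat profile maps to ρ = 0, p = 1 instead of NaN. Pairwise map and biome
comparisons use Spearman and two-sided Wilcoxon rank-sum with Holm
adjustment.

## The synthetic world

All stages are validated against a generator whose truth is known exactly.

**Grid and environment.** A 5° all-ocean world (36 × 72 cells) by default —
coastlines contribute nothing to these methods and would complicate the
oracles; 1° is available via configuration. Twelve monthly fields per
variable: SST falls from ≈ 30 °C at the equator to ≈ −2 °C at the poles
(cos^1.5 profile), macronutrients mirror SST with an equatorial upwelling
bump, chlorophyll and NPP carry an equatorial band plus a mid-to-high-
latitude enhancement, mixed layers deepen poleward and in local winter,
and each variable carries a smooth seeded noise field. Four latitudinal
regimes (tropical, temperate, polar N, polar S; boundaries 30° and 60°)
are encoded explicitly as step offsets on SSS, O2, Si and MLD — the Arctic
fresh and oxygen-rich, the Southern Ocean silicate-rich, temperate water
deeper-mixed — mirroring the real inter-hemispheric contrasts; without
them the two polar regimes would be statistically identical and no
clustering method could be expected to separate them. N\* and Si\* are
recomputed from the simulated parents. The per-variable amplitude,
seasonality and noise multipliers are configurable; zero seasonality and
noise collapse the 12 monthly fields onto the annual mean.

**Biomes.** Seven rectangles partitioning annual SST × NPP space
exhaustively (two high-latitude classes, two temperate/winter-subtropical,
and a productivity split of the warm ocean into gyre, transitional and
equatorial-upwelling classes). Overlapping or non-exhaustive rule sets are
rejected.

**Species.** Independent Gaussian responses per predictor (product
kernel), s_j(x) = exp(−Σ_k (x_k − μ_jk)²/2σ_jk²) — the simplest form
matching the response-curve assumptions of the model families. Trait
priors place mixotroph optima in warm, NO₃-poor water with a small
across-species spread (SST optimum SD 1.2 °C), strict phototrophs
intermediate (SD 4 °C), and strict phagotrophs widely scattered in SST
(SD 8 °C) and along the NPP axis — the concordant-generalist /
divergent-specialist contrast the pipeline must later detect, encoded as
the generating condition.

**Sampling.** Sites are cells drawn without replacement, months uniform
(the emulated compilations span seasons without a stated design), sampling
depths 5–30 m above the local mixed layer. Reads are a single multinomial
per site with shares ∝ s_j(site, month) · max_abundance_j (log-normal
abundances); total reads per sample equal the configured depth exactly, a
conservation law the tests assert. Optional Dirichlet-multinomial
overdispersion is available but off by default to keep the oracle math
exact. Read depth per sample is a free choice (the emulated databases do
not state one); the default is 10⁴.

**What the generator does not emulate.** PCR/primer bias, rRNA gene
copy-number variation (a known caveat of read-abundance interpretation in
dinoflagellates), coastlines, currents or dispersal limitation, and any
quantitative resemblance to real WOA/MODIS field statistics — only the
qualitative gradient structure. Passing tests therefore demonstrate that
the pipeline recovers the structure it was pointed at under a clean
sampling model, not that real-data inferences are unbiased.

## Identifiability of thermal optima (niche-recovery experiment)

With 10⁴ reads per sample, presence/absence detects relative suitability
down to roughly 10⁻³ of the community-dominant level, so a species'
presence envelope spans about ±4σ around its optimum and the committee
maps have flat tops. Two consequences shaped the recovery experiment's
design: (i) optima are drawn from U(4, 22) °C — an optimum near the
equatorial SST plateau (or beyond the attainable range) cannot be
localised by any presence-based method because the environment barely
varies there; (ii) niche breadths are narrow, U(0.8, 1.5) °C, keeping the
detection envelope a few degrees wide. The recovered optimum is the
centroid of the ≥ 95%-of-maximum plateau of the zonal-mean annual HSI
(`sdm.optimum_from_profile`) — the canonical tie-break for an argmax over
a flat top. Under these conditions the committee places the optimum
within ±2 °C for ≥ 80% of modelable species; under broad niches or
warm-edge optima it cannot, and that failure is informative about the
method, not about the code.

## Default problem sizes

Tests and the acceptance script run the 5° world with 60 species
(20 per strategy), 300 sites, 10⁴ reads per sample, 4 families × 5 CV
repetitions — the package's reference study conditions, which complete in
a few minutes on one CPU while leaving every qualitative contrast
detectable. The schedule-bookkeeping check uses the 5-entry family
registry (the duplicate-GLM slot) with 72 species, the configuration whose
fit count is 72 × 5 × 5 = 1800.

## Known limitations

- The all-ocean world has no land, so area weighting is the only
  geometry the spatial statistics are tested against.
- The generator's regimes and trait contrasts are deliberately strong;
  effect sizes in real metabarcoding compilations will be weaker and
  confounded by sampling design.
- The GAM and MARS members are compact in-package implementations built
  on sklearn primitives (spline bases + penalised logistic; hinge
  forward-selection + GCV pruning + logistic link) — adequate for
  committee membership, not drop-in replacements for mgcv or earth.
- Escoufier selection is greedy; like every forward selection it can miss
  a jointly-optimal subset, though it matches per-step exhaustive search
  by construction.
- p-values from the biome-level rank-sum tests treat grid cells as
  independent observations, ignoring spatial autocorrelation; with
  thousands of cells they are effectively descriptive.
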