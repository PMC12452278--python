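"""Per-species ensemble distribution models.

Presence/absence labels come straight from the read table (a site where the
species received no reads is a true absence — the sampling design observed
the whole community there). Each species gets a committee of models from
four families (logistic GLM with quadratic terms, spline-basis GAM, MARS
with hinge growth and GCV pruning, and a small weight-decayed neural net),
fitted over repeated stratified calibration/validation splits. Each member
carries the presence threshold that maximises the Jaccard index on its
calibration split; members whose validation Jaccard clears a retention
cut-off form the ensemble, and the species' habitat suitability at a cell
is the fraction of retained members voting "presence" there.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .community import CommunityTable
from .synth import EnvClimatology

THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


# ---------------------------------------------------------------------------
# presence/absence
# ---------------------------------------------------------------------------

@dataclass
class PresenceAbsence:
    species_id: str
    site_ids: list[str]
    labels: np.ndarray                 # 1 = at least one read, 0 = sampled absent
    predictors: pd.DataFrame           # per-site environmental values


@dataclass
class SkipMarker:
    species_id: str
    reason: str


def build_pa(table: CommunityTable, species_id: str,
             predictors: pd.DataFrame,
             min_occurrences: int = 20) -> PresenceAbsence | SkipMarker:
    """Presence/absence labels for one species over the sampled sites.

    Returns a :class:`SkipMarker` when the species has fewer than
    ``min_occurrences`` presences, or no absences at all (present
    everywhere: unmodelable).
    """
    if species_id not in table.counts.index:
        raise KeyError(f"species {species_id!r} not in table")
    counts = table.counts.loc[species_id]
    labels = (counts.to_numpy() > 0).astype(int)
    n_pres = int(labels.sum())
    if n_pres < min_occurrences:
        return SkipMarker(species_id, f"only {n_pres} presences (< {min_occurrences})")
    if n_pres == len(labels):
        return SkipMarker(species_id, "present at every site: no absences")
    pred = predictors.loc[list(table.counts.columns)]
    return PresenceAbsence(species_id=species_id, site_ids=list(table.counts.columns),
                           labels=labels, predictors=pred)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def jaccard_index(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """|A n B| / |A u B| over the presence sets; 1.0 when both are empty."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    union = np.logical_or(y_true, y_pred).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(y_true, y_pred).sum() / union)


def optimal_threshold(y_true: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Scan the 0.01..0.99 grid for the threshold maximising the Jaccard
    index; ties break toward the lower threshold."""
    y_true = np.asarray(y_true).astype(bool)
    p = np.asarray(p, dtype=float)
    pred = p[None, :] >= THRESHOLD_GRID[:, None]
    tp = (pred & y_true[None, :]).sum(axis=1)
    union = (pred | y_true[None, :]).sum(axis=1)
    jac = np.where(union == 0, 1.0, tp / np.maximum(union, 1))
    best = int(np.argmax(jac))          # argmax returns the first (lowest) tie
    return float(THRESHOLD_GRID[best]), float(jac[best])


# ---------------------------------------------------------------------------
# predictor selection
# ---------------------------------------------------------------------------

def screen_collinearity(predictors: pd.DataFrame,
                        importance: dict[str, float] | pd.Series,
                        rho_cut: float = 0.7) -> list[str]:
    """Drop the less important member of every highly rank-correlated pair.

    Pairs are visited by descending |Spearman rho|; when both members of a
    pair with |rho| > rho_cut still survive, the lower-importance one is
    removed (ties: the later column). Deterministic; returns survivors in
    original column order.
    """
    importance = pd.Series(importance)
    missing = set(predictors.columns) - set(importance.index)
    if missing:
        raise ValueError(f"importance missing for: {sorted(missing)}")
    cols = list(predictors.columns)
    rho = predictors.corr(method="spearman").to_numpy()
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = abs(rho[i, j])
            if np.isfinite(r) and r > rho_cut:
                pairs.append((r, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(cols)
    for _, i, j in pairs:
        a, b = cols[i], cols[j]
        if a in alive and b in alive:
            if importance[a] >= importance[b]:
                alive.discard(b)
            else:
                alive.discard(a)
    return [c for c in cols if c in alive]


def preliminary_importance(pa: PresenceAbsence, seed: int = 0,
                           n_permutations: int = 5) -> pd.Series:
    """Permutation importance from a preliminary quadratic logistic model.

    importance(v) = 1 - mean Pearson correlation between model predictions
    on the data and predictions with column v permuted (5 seeded
    permutations), clipped to [0, 1]; a constant column permutes to itself
    and scores 0. Falls back to |point-biserial correlation| when the
    preliminary fit is degenerate.
    """
    X = pa.predictors.to_numpy(dtype=float)
    y = pa.labels
    rng = np.random.default_rng(seed)
    try:
        member = GLMMember(seed=seed).fit(X, y)
        p0 = member.predict_proba(X)
        if np.std(p0) == 0:
            raise FamilyFitError("constant preliminary predictions")
        out = {}
        for j, name in enumerate(pa.predictors.columns):
            if np.std(X[:, j]) == 0:
                out[name] = 0.0   # permuting a constant column is a no-op
                continue
            corrs = []
            for _ in range(n_permutations):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                pp = member.predict_proba(Xp)
                if np.std(pp) == 0:
                    corrs.append(0.0)
                else:
                    corrs.append(np.corrcoef(p0, pp)[0, 1])
            out[name] = float(np.clip(1.0 - np.mean(corrs), 0.0, 1.0))
        return pd.Series(out)
    except (FamilyFitError, np.linalg.LinAlgError, ValueError):
        out = {}
        for j, name in enumerate(pa.predictors.columns):
            x = X[:, j]
            out[name] = 0.0 if np.std(x) == 0 else abs(float(stats.pointbiserialr(y, x)[0]))
        return pd.Series(out)


def select_predictors(pa: PresenceAbsence, rho_cut: float = 0.7,
                      top_k: int = 4, seed: int = 0) -> list[str]:
    """Species-specific predictor set: collinearity-screened survivors
    ranked by preliminary importance, top ``top_k``."""
    imp = preliminary_importance(pa, seed=seed)
    surv = screen_collinearity(pa.predictors, imp, rho_cut=rho_cut)
    ranked = sorted(surv, key=lambda c: (-imp[c], list(pa.predictors.columns).index(c)))
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------

class FamilyFitError(RuntimeError):
    pass


class _Member:
    """Base for family members: standardises inputs, predicts probabilities."""

    family = "?"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def _design(self, Z: np.ndarray) -> np.ndarray:
        return Z

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise FamilyFitError("single-class training data")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self._fit_core(self._design(Z), y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = self.scaler_.transform(X)
        p = self._predict_core(self._design(Z))
        return np.clip(p, 0.0, 1.0)


class GLMMember(_Member):
    """Logistic regression with linear + quadratic (squared) terms."""

    family = "GLM"

    def _design(self, Z: np.ndarray) -> np.ndarray:
        return np.hstack([Z, Z ** 2])

    def _fit_core(self, D: np.ndarray, y: np.ndarray) -> None:
        self.clf_ = LogisticRegression(C=1e3, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.clf_.fit(D, y)

    def _predict_core(self, D: np.ndarray) -> np.ndarray:
        return self.clf_.predict_proba(D)[:, 1]

    @property
    def linear_coefficients_(self) -> np.ndarray:
        """Linear-term coefficients on the original predictor scale."""
        k = len(self.scaler_.scale_)
        return self.clf_.coef_[0, :k] / self.scaler_.scale_


class GAMMember(_Member):
    """Additive logistic model on per-predictor cubic spline bases with a
    ridge penalty as the smoother (modest basis size against overfitting)."""

    family = "GAM"

    def __init__(self, seed: int = 0, n_knots: int = 5, degree: int = 3, C: float = 1.0):
        super().__init__(seed)
        self.n_knots = n_knots
        self.degree = degree
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise FamilyFitError("single-class training data")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.spline_ = SplineTransformer(n_knots=self.n_knots, degree=self.degree,
                                         extrapolation="constant").fit(Z)
        D = self.spline_.transform(Z)
        self.clf_ = LogisticRegression(C=self.C, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.clf_.fit(D, y)
        return self

    def predict_proba(self, X):
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return np.clip(self.clf_.predict_proba(self.spline_.transform(Z))[:, 1], 0, 1)


class MARSMember(_Member):
    """Multivariate adaptive regression splines, logistic link.

    Forward pass greedily adds reflected hinge pairs max(0, x - t) /
    max(0, t - x) (knots at training quantiles) that most reduce the
    least-squares RSS against the 0/1 labels; the backward pass prunes basis
    functions by generalized cross-validation; a logistic fit on the pruned
    basis supplies probabilities.
    """

    family = "MARS"

    def __init__(self, seed: int = 0, max_terms: int = 9, gcv_penalty: float = 3.0,
                 n_knots: int = 7):
        super().__init__(seed)
        self.max_terms = max_terms
        self.gcv_penalty = gcv_penalty
        self.n_knots = n_knots

    def _hinges(self, Z: np.ndarray) -> np.ndarray:
        cols = [np.ones(Z.shape[0])]
        for var, knot, sign in self.basis_:
            h = sign * (Z[:, var] - knot)
            cols.append(np.maximum(h, 0.0))
        return np.column_stack(cols)

    @staticmethod
    def _rss(D: np.ndarray, y: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        r = y - D @ beta
        return float(r @ r)

    def _fit_core(self, Z: np.ndarray, y: np.ndarray) -> None:
        n, k = Z.shape
        yf = y.astype(float)
        qs = np.linspace(0.1, 0.9, self.n_knots)
        candidates = []
        for var in range(k):
            for knot in np.unique(np.quantile(Z[:, var], qs)):
                candidates.append((var, float(knot)))
        self.basis_: list[tuple[int, float, float]] = []
        D = np.ones((n, 1))
        rss = self._rss(D, yf)
        while len(self.basis_) < self.max_terms - 1:
            best = None
            for var, knot in candidates:
                pair = np.column_stack([
                    np.maximum(Z[:, var] - knot, 0.0),
                    np.maximum(knot - Z[:, var], 0.0),
                ])
                trial = np.hstack([D, pair])
                r = self._rss(trial, yf)
                if best is None or r < best[0] - 1e-12:
                    best = (r, var, knot, pair)
            if best is None or best[0] > rss - 1e-10 * max(rss, 1.0):
                break
            rss, var, knot, pair = best
            self.basis_.append((var, knot, 1.0))
            self.basis_.append((var, knot, -1.0))
            D = np.hstack([D, pair])
        # backward pruning by GCV
        def gcv(basis):
            Dm = self._hinges_for(Z, basis)
            m = Dm.shape[1]
            c = m + self.gcv_penalty * (m - 1) / 2.0
            denom = (1.0 - c / n) ** 2
            if denom <= 0:
                return np.inf
            return self._rss(Dm, yf) / n / denom

        basis = list(self.basis_)
        best_basis, best_gcv = list(basis), gcv(basis)
        while basis:
            trial_scores = []
            for i in range(len(basis)):
                trial = basis[:i] + basis[i + 1:]
                trial_scores.append((gcv(trial), i))
            g, i = min(trial_scores)
            basis = basis[:i] + basis[i + 1:]
            if g < best_gcv:
                best_gcv, best_basis = g, list(basis)
        self.basis_ = best_basis
        D = self._hinges(Z)
        self.clf_ = LogisticRegression(C=1e3, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.clf_.fit(D, y)

    def _hinges_for(self, Z: np.ndarray, basis) -> np.ndarray:
        cols = [np.ones(Z.shape[0])]
        for var, knot, sign in basis:
            cols.append(np.maximum(sign * (Z[:, var] - knot), 0.0))
        return np.column_stack(cols)

    def _predict_core(self, Z: np.ndarray) -> np.ndarray:
        return self.clf_.predict_proba(self._hinges(Z))[:, 1]


class ANNMember(_Member):
    """Single-hidden-layer perceptron (<= 8 units) with weight decay and a
    seeded deterministic initialisation."""

    family = "ANN"

    def __init__(self, seed: int = 0, hidden: int = 6, alpha: float = 1e-2,
                 max_iter: int = 400):
        super().__init__(seed)
        self.hidden = hidden
        self.alpha = alpha
        self.max_iter = max_iter

    def _fit_core(self, D: np.ndarray, y: np.ndarray) -> None:
        self.clf_ = MLPClassifier(hidden_layer_sizes=(min(self.hidden, 8),),
                                  alpha=self.alpha, solver="lbfgs",
                                  max_iter=self.max_iter,
                                  random_state=self.seed % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.clf_.fit(D, y)

    def _predict_core(self, D: np.ndarray) -> np.ndarray:
        return self.clf_.predict_proba(D)[:, 1]


FAMILY_REGISTRY: dict[str, type] = {
    "GLM": GLMMember,
    "GAM": GAMMember,
    "MARS": MARSMember,
    "ANN": ANNMember,
}

#: five-slot registry (duplicate GLM entry) matching workflows that count
#: five algorithms per species
EXTENDED_FAMILY_REGISTRY: dict[str, type] = {**FAMILY_REGISTRY, "GLM2": GLMMember}


def derive_seed(base: int, *parts) -> int:
    """Stable sub-seed < 2**31 from a base seed and arbitrary labels."""
    h = hashlib.sha256(":".join([str(base), *map(str, parts)]).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


def fit_family(pa: PresenceAbsence, family: str, seed: int = 0,
               registry: dict[str, type] | None = None) -> _Member:
    """Fit one family on the full presence/absence data (no split)."""
    registry = registry or FAMILY_REGISTRY
    if family not in registry:
        raise KeyError(f"unknown family {family!r}")
    return registry[family](seed=seed).fit(pa.predictors.to_numpy(dtype=float), pa.labels)


def schedule_fits(species_ids, families, n_reps: int) -> list[tuple[str, str, int]]:
    """The full (species, family, cv_rep) fit schedule."""
    return [(s, f, r) for s in species_ids for f in families for r in range(n_reps)]


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    species_id: str
    family: str
    cv_rep: int
    model: _Member | None
    calibration_threshold: float
    jaccard_calibration: float
    jaccard_validation: float
    retained: bool
    failed: bool = False
    failure_reason: str = ""


@dataclass
class EnsembleSpec:
    species_id: str
    members: list[FittedModel]
    predictor_names: list[str]
    n_trained: int

    @property
    def retained_members(self) -> list[FittedModel]:
        return [m for m in self.members if m.retained]

    @property
    def n_retained(self) -> int:
        return len(self.retained_members)


class SDMEnsemble(BaseEstimator):
    """Cross-validated multi-family committee for one species.

    For every (family, repetition): fit on a stratified calibration split,
    pick the calibration threshold maximising the Jaccard index, score the
    validation split at that threshold; retain members with validation
    Jaccard above ``retention_cutoff``.
    """

    def __init__(self, families: tuple[str, ...] = ("GLM", "GAM", "MARS", "ANN"),
                 n_reps: int = 5, test_size: float = 0.2,
                 retention_cutoff: float = 0.3, random_state: int = 0,
                 registry: dict[str, type] | None = None,
                 species_id: str = "species"):
        self.families = families
        self.n_reps = n_reps
        self.test_size = test_size
        self.retention_cutoff = retention_cutoff
        self.random_state = random_state
        self.registry = registry
        self.species_id = species_id

    def fit(self, X, y):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        registry = self.registry or FAMILY_REGISTRY
        counts = np.bincount(y, minlength=2)
        n_val = int(np.floor(self.test_size * len(y)))
        if min(counts) < 2 or n_val < 2 or min(counts) * self.test_size < 1:
            raise ValueError(
                "a label stratum would be empty under the requested split; "
                "lower test_size or provide more data")
        splitter = StratifiedShuffleSplit(n_splits=self.n_reps,
                                          test_size=self.test_size,
                                          random_state=self.random_state % (2 ** 31))
        Xa = X.to_numpy(dtype=float)
        members: list[FittedModel] = []
        for rep, (cal, val) in enumerate(splitter.split(Xa, y)):
            for fam in self.families:
                seed = derive_seed(self.random_state, self.species_id, fam, rep)
                try:
                    member = registry[fam](seed=seed).fit(Xa[cal], y[cal])
                    p_cal = member.predict_proba(Xa[cal])
                    thr, j_cal = optimal_threshold(y[cal], p_cal)
                    p_val = member.predict_proba(Xa[val])
                    j_val = jaccard_index(y[val], p_val >= thr)
                    members.append(FittedModel(
                        species_id=self.species_id, family=fam, cv_rep=rep,
                        model=member, calibration_threshold=thr,
                        jaccard_calibration=j_cal, jaccard_validation=j_val,
                        retained=j_val > self.retention_cutoff))
                except (FamilyFitError, np.linalg.LinAlgError) as exc:
                    members.append(FittedModel(
                        species_id=self.species_id, family=fam, cv_rep=rep,
                        model=None, calibration_threshold=np.nan,
                        jaccard_calibration=np.nan, jaccard_validation=np.nan,
                        retained=False, failed=True, failure_reason=str(exc)))
        self.members_ = members
        self.retained_members_ = [m for m in members if m.retained]
        self.n_trained_ = len(members)
        self.n_retained_ = len(self.retained_members_)
        self.feature_names_ = list(X.columns)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Committee fraction: share of retained members voting presence."""
        if not self.retained_members_:
            raise ValueError("empty ensemble: no retained members")
        Xa = pd.DataFrame(X)[self.feature_names_].to_numpy(dtype=float)
        votes = np.stack([
            (m.model.predict_proba(Xa) >= m.calibration_threshold).astype(float)
            for m in self.retained_members_])
        return votes.mean(axis=0)


def cross_validate(pa: PresenceAbsence,
                   families: tuple[str, ...] = ("GLM", "GAM", "MARS", "ANN"),
                   n_reps: int = 5, split: float = 0.2,
                   retention_cutoff: float = 0.3, seed: int = 0,
                   registry: dict[str, type] | None = None) -> tuple[EnsembleSpec, SDMEnsemble]:
    """Fit the cross-validated committee for one species."""
    est = SDMEnsemble(families=tuple(families), n_reps=n_reps, test_size=split,
                      retention_cutoff=retention_cutoff, random_state=seed,
                      registry=registry, species_id=pa.species_id)
    est.fit(pa.predictors, pa.labels)
    spec = EnsembleSpec(species_id=pa.species_id, members=est.members_,
                        predictor_names=list(pa.predictors.columns),
                        n_trained=est.n_trained_)
    return spec, est


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

@dataclass
class HSIMap:
    species_id: str
    monthly: np.ndarray   # (12, nlat, nlon) committee fractions in [0, 1]

    @property
    def annual(self) -> np.ndarray:
        return self.monthly.mean(axis=0)


def project(ensemble: EnsembleSpec, env: EnvClimatology) -> HSIMap:
    """Project the retained committee on the 12 monthly predictor fields.

    Per member and month: predict a probability per cell and binarise at the
    member's calibration threshold; the species' monthly habitat suitability
    is the fraction of members predicting presence.
    """
    retained = ensemble.retained_members
    if not retained:
        raise ValueError(f"empty ensemble for {ensemble.species_id}: nothing to project")
    for name in ensemble.predictor_names:
        if name not in env.monthly:
            raise KeyError(f"missing predictor field {name!r} in climatology")
    shape = env.grid.shape
    monthly = np.empty((12, *shape))
    for m in range(12):
        Xm = np.column_stack([env.monthly[n][m].ravel() for n in ensemble.predictor_names])
        votes = np.zeros(Xm.shape[0])
        for mem in retained:
            votes += (mem.model.predict_proba(Xm) >= mem.calibration_threshold)
        monthly[m] = (votes / len(retained)).reshape(shape)
    return HSIMap(species_id=ensemble.species_id, monthly=monthly)


def optimum_from_profile(profile: np.ndarray, env_values: np.ndarray,
                         top_fraction: float = 0.95) -> float:
    """Environmental value maximising a suitability profile.

    Committee suitability profiles have flat tops (every member votes
    presence across the core of the niche), so the maximiser is an interval
    rather than a point; the estimate is the mean of the environmental
    values over the near-maximal plateau (profile >= top_fraction * max).
    """
    profile = np.asarray(profile, dtype=float)
    env_values = np.asarray(env_values, dtype=float)
    if profile.shape != env_values.shape:
        raise ValueError("profile and environmental values must align")
    if not np.isfinite(profile).any() or profile.max() <= 0:
        raise ValueError("profile has no positive values")
    top = profile >= top_fraction * profile.max()
    return float(env_values[top].mean())


def ensemble_manifest(specs: list[EnsembleSpec]) -> pd.DataFrame:
    rows = []
    for spec in specs:
        for m in spec.members:
            rows.append({
                "species_id": m.species_id, "family": m.family, "cv_rep": m.cv_rep,
                "threshold": m.calibration_threshold,
                "jaccard_validation": m.jaccard_validation,
                "retained": m.retained, "failed": m.failed,
            })
    return pd.DataFrame(rows)
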