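"""Constrained ordination from first principles.

Redundancy analysis (RDA) is the principal component analysis of the fitted
values of a multivariate linear regression of a (typically
Hellinger-transformed) community matrix Y on standardized environmental
predictors X. Dimensionality of the response is reduced beforehand with
Escoufier's equivalent-vectors method — a greedy forward selection of
species columns maximising the RV matrix correlation with the full table —
and predictors are pruned by backward selection under an AIC parsimony
criterion computed from the multivariate residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .envspace import _orient_components


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def rv_coefficient(A, B) -> float:
    """Escoufier's RV coefficient between two matrices on the same rows.

    RV = tr(S_AB S_BA) / sqrt(tr(S_AA^2) tr(S_BB^2)) with S the
    cross-product matrices of the column-centered inputs; 1 for identical
    configurations (up to rotation/scaling), near 0 for unrelated ones.
    """
    A = _center(np.atleast_2d(np.asarray(A, dtype=float).T).T)
    B = _center(np.atleast_2d(np.asarray(B, dtype=float).T).T)
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have the same number of rows")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    na = np.linalg.norm(A.T @ A)
    nb = np.linalg.norm(B.T @ B)
    if na == 0 or nb == 0:
        raise ValueError("all-zero matrix after centering")
    num = np.linalg.norm(A.T @ B) ** 2
    return float(num / (na * nb))


@dataclass
class EscoufierSelection:
    ordered_selected_ids: list
    rv_trajectory: list[float]
    threshold: float


def subset_rv(M: np.ndarray, selected: list[int]) -> float:
    """Equivalent-vectors score of a column subset: RV between the centered
    table and its projection onto the span of the selected columns.

    A column lying in the span of the selection (e.g. an exact duplicate)
    adds exactly zero, and the score reaches 1 exactly when the selection
    spans the table's column space.
    """
    A = M[:, selected]
    B, *_ = np.linalg.lstsq(A, M, rcond=None)
    return rv_coefficient(M, A @ B)


class EscoufierSelector(BaseEstimator):
    """Greedy forward selection of the response columns that best represent
    the whole table (Escoufier's equivalent vectors).

    At each step the column whose addition maximises the subset RV score is
    added (ties broken by column order); selection stops when the score
    reaches ``threshold`` or ``max_k`` columns are selected.
    """

    def __init__(self, threshold: float = 0.9, max_k: int | None = None):
        self.threshold = threshold
        self.max_k = max_k

    def fit(self, Y, y=None):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        Y = pd.DataFrame(Y)
        if Y.shape[1] == 0 or Y.shape[0] < 2:
            raise ValueError("empty response matrix")
        M = _center(Y.to_numpy(dtype=float))
        if np.all(M == 0):
            raise ValueError("all-zero response matrix")
        p = M.shape[1]
        max_k = min(self.max_k or p, p)
        selected: list[int] = []
        trajectory: list[float] = []
        # constant (all-zero after centering) columns are never candidates
        remaining = [j for j in range(p) if np.any(M[:, j] != 0)]
        while remaining and len(selected) < max_k:
            best_j, best_rv = None, -np.inf
            for j in remaining:
                rv = subset_rv(M, selected + [j])
                if rv > best_rv + 1e-12:   # strict improvement; ties keep first
                    best_rv, best_j = rv, j
            selected.append(best_j)
            remaining.remove(best_j)
            trajectory.append(best_rv)
            if best_rv >= self.threshold - 1e-12:
                break
        self.selected_indices_ = selected
        self.selected_ids_ = [Y.columns[j] for j in selected]
        self.rv_trajectory_ = trajectory
        return self

    def transform(self, Y) -> pd.DataFrame:
        check_is_fitted(self, "selected_ids_")
        return pd.DataFrame(Y)[self.selected_ids_]


def escoufier_select(Y, threshold: float = 0.9,
                     max_k: int | None = None) -> EscoufierSelection:
    sel = EscoufierSelector(threshold=threshold, max_k=max_k).fit(Y)
    return EscoufierSelection(ordered_selected_ids=sel.selected_ids_,
                              rv_trajectory=sel.rv_trajectory_,
                              threshold=threshold)


class CollinearityError(np.linalg.LinAlgError):
    pass


class RDA(BaseEstimator):
    """Redundancy analysis: PCA of the fitted values of Y ~ X.

    Parameters
    ----------
    standardize : center and scale the predictor columns (default True); the
        response is always column-centered.

    Fitted attributes
    -----------------
    canonical_eigenvalues_, residual_eigenvalues_ : variances of the
        constrained and unconstrained axes; together they sum to the total
        variance of the centered response.
    proportion_explained_ : canonical eigenvalues over total variance.
    r_squared_, adjusted_r_squared_ : SS(fitted)/SS(total) and its
        Ezekiel-style small-sample adjustment.
    site_scores_ : constrained sample scores (fitted values on the axes).
    species_scores_ : response-column loadings scaled by axis magnitude.
    biplot_scores_ : predictor correlations with the constrained axes.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, Y):
        X = pd.DataFrame(X)
        Y = pd.DataFrame(Y)
        n, m = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y must have aligned rows")
        if n <= m + 1:
            raise ValueError("need n_rows > n_predictors + 1")
        self.predictor_names_ = list(X.columns)
        self.response_names_ = list(Y.columns)
        Xm = X.to_numpy(dtype=float)
        Xc = Xm - Xm.mean(axis=0)
        if self.standardize:
            sd = Xm.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise CollinearityError(
                    f"constant predictor(s): {list(X.columns[sd == 0])}")
            Xc = Xc / sd
        Yc = _center(Y.to_numpy(dtype=float))

        xtx = Xc.T @ Xc
        if np.linalg.matrix_rank(xtx) < m:
            raise CollinearityError(
                "singular X'X: predictors are collinear; screen the "
                "predictor set (e.g. pairwise correlation) before fitting")
        B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        Yhat = Xc @ B
        Yres = Yc - Yhat

        _, s_can, vt_can = np.linalg.svd(Yhat, full_matrices=False)
        _, s_res, _ = np.linalg.svd(Yres, full_matrices=False)
        eig_can = s_can ** 2 / (n - 1)
        eig_res = s_res ** 2 / (n - 1)
        n_axes = min(m, Y.shape[1])
        eig_can = eig_can[:n_axes]
        vt_can = _orient_components(vt_can[:n_axes])

        total = (Yc ** 2).sum() / (n - 1)
        ss_tot = (Yc ** 2).sum()
        ss_fit = (Yhat ** 2).sum()
        r2 = ss_fit / ss_tot
        self.canonical_eigenvalues_ = eig_can
        self.residual_eigenvalues_ = eig_res[eig_res > 1e-12 * max(total, 1.0)]
        self.total_variance_ = float(total)
        self.proportion_explained_ = eig_can / total
        self.r_squared_ = float(r2)
        self.adjusted_r_squared_ = float(1 - (1 - r2) * (n - 1) / (n - m - 1))
        self.site_scores_ = Yhat @ vt_can.T
        axes = [f"RDA{i+1}" for i in range(n_axes)]
        self.species_scores_ = pd.DataFrame(
            (vt_can * np.sqrt(eig_can)[:, None]).T, index=Y.columns, columns=axes)
        # predictor-axis correlations; constant scores give 0
        bip = np.zeros((m, n_axes))
        for j in range(m):
            for a in range(n_axes):
                sc = self.site_scores_[:, a]
                if sc.std() > 0 and Xc[:, j].std() > 0:
                    bip[j, a] = np.corrcoef(Xc[:, j], sc)[0, 1]
        self.biplot_scores_ = pd.DataFrame(bip, index=X.columns, columns=axes)
        self.coef_ = B
        self.n_samples_ = n
        return self


def rda_fit(Y, X, standardize: bool = True) -> RDA:
    """Fit an RDA of response Y (rows = samples) on predictors X."""
    return RDA(standardize=standardize).fit(X, Y)


def _rda_rss(Y: np.ndarray, X: np.ndarray) -> float:
    Xc = _center(X)
    Yc = _center(Y)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return float(((Yc - Xc @ B) ** 2).sum())


def _aic(Y: np.ndarray, X: np.ndarray | None, n: int) -> float:
    """AIC for a multivariate linear constraint: n ln(RSS/n) + 2(m + 1)."""
    if X is None or X.shape[1] == 0:
        rss = float((_center(Y) ** 2).sum())
        m = 0
    else:
        rss = _rda_rss(Y, X)
        m = X.shape[1]
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (m + 1)


def aic_backward_select(Y, X, candidate_names: list[str] | None = None,
                        direction: str = "backward") -> tuple[list[str], list[tuple[str, float]]]:
    """Stepwise predictor selection under the multivariate-RSS AIC.

    Backward (default): iteratively drop the predictor whose removal most
    decreases the AIC; stop when no removal decreases it. Forward: start
    empty and add while the AIC decreases. Deterministic; returns the
    selected names and the (action, AIC) trace, whose first entry is the
    starting model.
    """
    Y = pd.DataFrame(Y).to_numpy(dtype=float)
    X = pd.DataFrame(X)
    names = list(candidate_names) if candidate_names is not None else list(X.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 candidate predictors")
    n = Y.shape[0]
    Xs = X[names].to_numpy(dtype=float)
    sd = Xs.std(axis=0, ddof=1)
    Xs = (Xs - Xs.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    cols = {nm: Xs[:, j] for j, nm in enumerate(names)}

    def matrix(sel: list[str]) -> np.ndarray | None:
        return np.column_stack([cols[nm] for nm in sel]) if sel else None

    if direction == "backward":
        current = list(names)
        trace = [("<start>", _aic(Y, matrix(current), n))]
        while len(current) > 0:
            best = None
            for nm in current:
                trial = [c for c in current if c != nm]
                a = _aic(Y, matrix(trial), n)
                if best is None or a < best[1] - 1e-12:
                    best = (nm, a)
            if best[1] < trace[-1][1] - 1e-12:
                current.remove(best[0])
                trace.append((f"-{best[0]}", best[1]))
            else:
                break
        return current, trace
    elif direction == "forward":
        current: list[str] = []
        trace = [("<start>", _aic(Y, None, n))]
        remaining = list(names)
        while remaining:
            best = None
            for nm in remaining:
                a = _aic(Y, matrix(current + [nm]), n)
                if best is None or a < best[1] - 1e-12:
                    best = (nm, a)
            if best[1] < trace[-1][1] - 1e-12:
                current.append(best[0])
                remaining.remove(best[0])
                trace.append((f"+{best[0]}", best[1]))
            else:
                break
        return current, trace
    raise ValueError("direction must be 'backward' or 'forward'")
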