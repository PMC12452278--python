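"""Environmental space: derived nutrient indices, PCA with supplementary
variables, and hierarchical classification on component scores (HCPC).

The PCA is the standard correlation-matrix decomposition (centered,
unit-variance columns by default). Supplementary columns never influence
the decomposition; only their Pearson correlations with the component
scores are reported — the device used to place habitat-suitability fields
inside the abiotic environmental space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: the 11 annual variables entering the site-level PCA
SITE_PCA_VARIABLES = ("SST", "SSS", "NO3", "PO4", "Si", "MLD", "PAR", "O2",
                      "Sistar", "Nstar", "Chla")

#: the full 13-variable set used for the grid-cell environmental space
GRID_PCA_VARIABLES = SITE_PCA_VARIABLES + ("PIC", "NPP")


def derive_indices(env: pd.DataFrame) -> pd.DataFrame:
    """Nutrient-excess indices: Nstar = NO3 - 16*PO4, Sistar = Si - NO3."""
    for col in ("NO3", "PO4", "Si"):
        if col not in env.columns:
            raise KeyError(f"missing parent column {col!r}")
    out = env.copy()
    out["Nstar"] = env["NO3"] - 16.0 * env["PO4"]
    out["Sistar"] = env["Si"] - env["NO3"]
    return out


def _orient_components(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude element is positive."""
    flips = np.sign(components[np.arange(components.shape[0]),
                               np.abs(components).argmax(axis=1)])
    flips[flips == 0] = 1.0
    return components * flips[:, None]


class SupplementaryPCA(BaseEstimator, TransformerMixin):
    """PCA with optional supplementary quantitative columns.

    Parameters
    ----------
    standardize : center and scale columns to unit variance (default True).
    n_components : number of components to retain (default: all).

    Fitted attributes
    -----------------
    eigenvalues_ : variances of the scores (non-increasing).
    explained_variance_ratio_ : fractions summing to 1 over all components.
    components_ : (n_components, n_vars) unit eigenvectors, oriented so the
        largest-magnitude element of each is positive.
    loadings_ : components scaled by sqrt(eigenvalue); for standardized
        input these are variable-component correlations.
    scores_ : (n_rows, n_components) sample scores of the training data.
    supplementary_correlations_ : DataFrame (supplementary x components) of
        Pearson correlations with the scores; constant supplementary columns
        get 0 and are listed in ``supplementary_degenerate_``.
    """

    def __init__(self, standardize: bool = True, n_components: int | None = None):
        self.standardize = standardize
        self.n_components = n_components

    def _process(self, X: np.ndarray) -> np.ndarray:
        Z = X - self.mean_
        if self.standardize:
            Z = Z / self.scale_
        return Z

    def fit(self, X, y=None, supplementary: pd.DataFrame | None = None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("PCA needs at least 2 rows and 2 columns")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        A = X.to_numpy(dtype=float)
        self.mean_ = A.mean(axis=0)
        sd = A.std(axis=0, ddof=1)
        if self.standardize and np.any(sd == 0):
            bad = list(X.columns[sd == 0])
            raise ValueError(f"constant column(s) under standardization: {bad}")
        self.scale_ = np.where(sd == 0, 1.0, sd)
        Z = self._process(A)
        n = Z.shape[0]
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        eig = s ** 2 / (n - 1)
        ncomp = self.n_components or len(eig)
        vt = _orient_components(vt)
        self.eigenvalues_ = eig[:ncomp]
        total = eig.sum()
        self.explained_variance_ratio_ = (eig / total)[:ncomp]
        self.components_ = vt[:ncomp]
        self.loadings_ = pd.DataFrame(
            (vt[:ncomp] * np.sqrt(self.eigenvalues_)[:, None]).T,
            index=X.columns, columns=[f"PC{i+1}" for i in range(ncomp)])
        self.scores_ = Z @ vt[:ncomp].T
        self.n_samples_ = n
        if supplementary is not None:
            self.set_supplementary(supplementary)
        else:
            self.supplementary_correlations_ = None
            self.supplementary_degenerate_ = []
        return self

    def set_supplementary(self, supplementary: pd.DataFrame) -> pd.DataFrame:
        """Correlate supplementary columns with the fitted scores."""
        check_is_fitted(self, "scores_")
        supplementary = pd.DataFrame(supplementary)
        if supplementary.shape[0] != self.n_samples_:
            raise ValueError("supplementary rows must match the fitted data")
        ncomp = self.scores_.shape[1]
        corrs = np.zeros((supplementary.shape[1], ncomp))
        degenerate = []
        sup = supplementary.to_numpy(dtype=float)
        for j, name in enumerate(supplementary.columns):
            v = sup[:, j]
            if np.std(v) == 0:
                degenerate.append(name)
                continue
            for c in range(ncomp):
                corrs[j, c] = np.corrcoef(v, self.scores_[:, c])[0, 1]
        self.supplementary_correlations_ = pd.DataFrame(
            corrs, index=supplementary.columns,
            columns=[f"PC{i+1}" for i in range(ncomp)])
        self.supplementary_degenerate_ = degenerate
        return self.supplementary_correlations_

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        Z = self._process(pd.DataFrame(X).to_numpy(dtype=float))
        return Z @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        Z = np.asarray(scores) @ self.components_
        if self.standardize:
            Z = Z * self.scale_
        return Z + self.mean_


def pca(env: pd.DataFrame, standardize: bool = True,
        supplementary: pd.DataFrame | None = None,
        n_components: int | None = None) -> SupplementaryPCA:
    """Fit a :class:`SupplementaryPCA`; the fitted estimator is the result."""
    return SupplementaryPCA(standardize=standardize, n_components=n_components).fit(
        env, supplementary=supplementary)


class HCPC(BaseEstimator, ClusterMixin):
    """Ward-linkage hierarchical clustering on leading PCA scores.

    Parameters
    ----------
    k : number of clusters.
    n_components : scores columns used; None picks the smallest number of
        components reaching ``variance_threshold`` cumulative variance.
    variance_threshold : cumulative explained-variance target (default 0.8).
    """

    def __init__(self, k: int = 4, n_components: int | None = None,
                 variance_threshold: float = 0.8):
        self.k = k
        self.n_components = n_components
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        """X: a fitted SupplementaryPCA, or a raw scores array."""
        if isinstance(X, SupplementaryPCA):
            scores = X.scores_
            ratios = X.explained_variance_ratio_
        else:
            scores = np.asarray(X, dtype=float)
            ratios = None
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k > scores.shape[0]:
            raise ValueError("k exceeds the number of rows")
        if self.n_components is not None:
            ncomp = self.n_components
            if ncomp > scores.shape[1]:
                raise ValueError("n_components exceeds available components")
        elif ratios is not None:
            cum = np.cumsum(ratios)
            ncomp = int(np.searchsorted(cum, self.variance_threshold) + 1)
            ncomp = min(ncomp, scores.shape[1])
        else:
            ncomp = scores.shape[1]
        self.retained_components_ = ncomp
        self.linkage_ = linkage(scores[:, :ncomp], method="ward")
        self.labels_ = fcluster(self.linkage_, t=self.k, criterion="maxclust")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def hcpc(pca_result: SupplementaryPCA, k: int,
         n_components: int | None = None) -> HCPC:
    """Cluster the rows of a fitted PCA on its leading scores."""
    return HCPC(k=k, n_components=n_components).fit(pca_result)
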