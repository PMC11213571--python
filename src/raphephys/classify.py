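"""Cell-type classification: standardize feature panels, PCA, Ward/Euclidean
hierarchical clustering on the leading principal components.

Two workflows mirror the analysis of dorsal-raphe recordings: a
five-feature panel (delay to first spike, AP drop rate, AP max rise rate,
AHP duration, capacitance) clustered on the first two PCs at k = 2 to
separate serotonergic- from dopaminergic-like cells, and a twenty-feature
panel clustered on the first three PCs at k = 4 for the broader cell-type
landscape. The core is the sklearn-style estimator
:class:`PCAWardCluster`; module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .features import FeaturePanel, panels_to_frame

#: the five parameters that best separate serotonergic from dopaminergic
#: profiles: shorter first-spike delay, ~zero ramp amplitude droop, faster
#: AP rise, longer AHP, larger capacitance in the serotonergic type
FIVE_FEATURES = (
    "delay_first_spike",
    "ap_drop_rate",
    "max_rise_rate",
    "ahp_duration",
    "capacitance",
)

#: the extended standardized panel for four-type clustering
TWENTY_FEATURES = (
    "spont_rate_or_zero",
    "rheobase",
    "ap_amplitude",
    "ap_duration",
    "max_rise_rate",
    "ap_threshold_v",
    "ap_peak_v",
    "ahp_amplitude",
    "ahp_duration",
    "ahp_trough_v",
    "ap_drop_rate",
    "delay_first_spike",
    "input_resistance",
    "sag_amplitude",
    "tau",
    "capacitance",
    "if_slope",
    "rebound_spiking",
    "max_step_rate",
    "min_hyperpol_v",
)


class DegenerateFeatureError(ValueError):
    """A feature column cannot be standardized (zero variance / too few values)."""


@dataclass
class FeatureMatrix:
    """Cells x features matrix with missingness mask and optional labels."""

    data: pd.DataFrame                     # NaN marks missing
    known_labels: pd.Series | None = None  # optional per-cell type labels

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        return self.data.notna()

    def complete_cases(self) -> "FeatureMatrix":
        keep = self.data.notna().all(axis=1)
        return FeatureMatrix(
            self.data.loc[keep],
            self.known_labels.loc[keep] if self.known_labels is not None else None,
        )


def matrix_from_panels(
    panels: list[FeaturePanel], features: tuple[str, ...] = FIVE_FEATURES
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from per-cell panels; absent features become
    NaN. The derived column ``spont_rate_or_zero`` is the spontaneous rate,
    0 Hz for cells classified silent (a true rate, not a missing value)."""
    df = panels_to_frame(panels).set_index("cell_id")
    if "spont_rate_or_zero" in features:
        rate = df["spont_rate"].copy()
        rate[df["spontaneous"] == False] = 0.0  # noqa: E712 - pandas mask
        df["spont_rate_or_zero"] = rate
    labels = df["putative_type"] if "putative_type" in df else None
    return FeatureMatrix(df[list(features)].astype(float), known_labels=labels)


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Column z-scores (mean 0, sample SD 1 over non-missing entries);
    missing entries stay missing. Zero-variance columns raise, naming the
    column."""
    df = matrix.data
    out = {}
    for col in df.columns:
        vals = df[col]
        n = vals.notna().sum()
        if n < 2:
            raise DegenerateFeatureError(f"feature {col!r} has fewer than 2 values")
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateFeatureError(f"feature {col!r} has zero variance")
        out[col] = (vals - vals.mean()) / sd
    return FeatureMatrix(pd.DataFrame(out, index=df.index), matrix.known_labels)


def pca(matrix: FeatureMatrix, n_components: int | None = None):
    """PCA of a standardized complete-case matrix.

    Returns (scores, loadings, explained_variance_ratio). Loadings are
    orthonormal columns; the sign convention fixes each component's
    largest-magnitude loading positive for cross-platform determinism.
    """
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires complete cases; filter with complete_cases()")
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 cells")
    n_components = n_components or min(X.shape)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # (features, components)
    # deterministic sign: largest |loading| entry positive per component
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return scores, loadings, model.explained_variance_ratio_


@dataclass
class ClusterResult:
    """Ward/Euclidean clustering output on leading PC scores."""

    labels: np.ndarray                 # flat labels in 1..k
    linkage: np.ndarray                # scipy 4-column merge table
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    known_labels: np.ndarray | None = None
    n_excluded: int = 0                # incomplete-case cells left out

    def confusion(self) -> pd.DataFrame | None:
        if self.known_labels is None:
            return None
        return pd.crosstab(
            pd.Series(self.known_labels, name="known"),
            pd.Series(self.labels, name="cluster"),
        )

    def purity(self) -> float | None:
        """Best-assignment agreement between clusters and known labels."""
        tab = self.confusion()
        if tab is None:
            return None
        from scipy.optimize import linear_sum_assignment

        cost = -tab.to_numpy()
        r, c = linear_sum_assignment(cost)
        return float(-cost[r, c].sum()) / float(len(self.labels))


class PCAWardCluster(ClusterMixin, BaseEstimator):
    """Standardize -> PCA -> Ward hierarchical clustering on leading PCs.

    Parameters
    ----------
    n_components : PCs carried into the clustering (2 or 3).
    n_clusters : flat clusters cut from the Ward tree.

    Fitted attributes: ``labels_`` (1..k), ``linkage_`` (scipy merge table,
    heights non-decreasing), ``scores_``, ``loadings_``,
    ``explained_variance_ratio_``.
    """

    def __init__(self, n_components: int = 2, n_clusters: int = 2):
        self.n_components = n_components
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if isinstance(X, FeatureMatrix):
            fm = X
        else:
            fm = FeatureMatrix(pd.DataFrame(np.asarray(X, dtype=float)))
        fm = fm.complete_cases()
        n = len(fm.data)
        if self.n_clusters > n:
            raise ValueError(f"k={self.n_clusters} exceeds n_cells={n}")
        z = standardize(fm)
        scores, loadings, evr = pca(z)
        lead = scores[:, : self.n_components]
        Z = linkage(lead, method="ward", metric="euclidean")
        self.labels_ = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        self.linkage_ = Z
        self.scores_ = scores
        self.loadings_ = loadings
        self.explained_variance_ratio_ = evr
        self.feature_names_in_ = fm.feature_names
        self.cell_index_ = list(fm.data.index)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def ward_cluster(scores: np.ndarray, n_components: int, k: int) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering over the first *n_components*
    PC scores, cut at *k* flat clusters."""
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    scores = np.asarray(scores, dtype=float)
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds n_cells={scores.shape[0]}")
    lead = scores[:, :n_components]
    Z = linkage(lead, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        labels=labels, linkage=Z, scores=scores,
        loadings=np.empty((0, 0)), explained_variance=np.empty(0),
    )


def _classify(
    panels: list[FeaturePanel],
    features: tuple[str, ...],
    n_components: int,
    k: int,
    min_cells: int,
) -> ClusterResult:
    fm = matrix_from_panels(panels, features)
    complete = fm.complete_cases()
    n_excluded = len(fm.data) - len(complete.data)
    if len(complete.data) < min_cells:
        raise ValueError(
            f"need >= {min_cells} complete-case cells, got {len(complete.data)}"
        )
    est = PCAWardCluster(n_components=n_components, n_clusters=k).fit(complete)
    known = (
        complete.known_labels.to_numpy() if complete.known_labels is not None else None
    )
    return ClusterResult(
        labels=est.labels_, linkage=est.linkage_, scores=est.scores_,
        loadings=est.loadings_, explained_variance=est.explained_variance_ratio_,
        feature_names=list(features), cell_ids=est.cell_index_,
        known_labels=known, n_excluded=n_excluded,
    )


def classify_two_types(panels: list[FeaturePanel]) -> ClusterResult:
    """Two-cluster classification on the five-feature panel (PCs 1-2)."""
    return _classify(panels, FIVE_FEATURES, n_components=2, k=2, min_cells=4)


def classify_four_types(panels: list[FeaturePanel]) -> ClusterResult:
    """Four-cluster classification on the twenty-feature panel (PCs 1-3)."""
    return _classify(panels, TWENTY_FEATURES, n_components=3, k=4, min_cells=8)
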