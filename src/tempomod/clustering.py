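"""Relative expression profiles and peak-ordered temporal modules.

Developmental genes are transformed to log2 relative profiles,

    values[t] = log2( rpkm_merged[g, t] / mean_t rpkm_merged[g, ·] ),

which removes the gene's absolute expression scale (the mean of 2^values
over time is exactly 1), so that Euclidean distance between profiles is a
profile-*shape* distance.  Profiles are clustered with kmeans (best of
``n_init`` seeded restarts by within-cluster sum of squares) and the
clusters are renumbered into developmental groups (DGs) 1..K by ascending
centroid peak time, the temporal order in which the modules turn on during
fruiting-body development.  For the canonical K=10 the DGs map onto the
morphological phases: DG1-2 down-regulated upon starvation, DG3-5
aggregation, DG6-7 the aggregation→sporulation transition, DG8-10
sporulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError

PHASES = ("down_regulated", "aggregation", "transition", "sporulation")

#: DG -> phase for the canonical 10-module decomposition.
DEFAULT_PHASE_MAP = {1: "down_regulated", 2: "down_regulated",
                     3: "aggregation", 4: "aggregation", 5: "aggregation",
                     6: "transition", 7: "transition",
                     8: "sporulation", 9: "sporulation", 10: "sporulation"}


class RelativeProfileTransformer(TransformerMixin, BaseEstimator):
    """Row-wise log2(x / row mean).  Stateless; requires strictly positive input."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        values = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if (values <= 0).any() or not np.isfinite(values).all():
            bad = np.where(~((values > 0) & np.isfinite(values)))[0][0]
            name = X.index[bad] if isinstance(X, pd.DataFrame) else bad
            raise ValidationError(
                f"relative profile undefined for gene {name!r}: "
                "all merged RPKM values must be positive and finite")
        out = np.log2(values / values.mean(axis=1, keepdims=True))
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def relative_profiles(rpkm_merged: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Log2 relative profiles for *genes* (default: all rows)."""
    sub = rpkm_merged if genes is None else rpkm_merged.loc[list(genes)]
    return RelativeProfileTransformer().transform(sub)


def _dg_order(centroids: np.ndarray) -> np.ndarray:
    """Permutation of raw cluster labels into DG order.

    Ascending centroid argmax time; ties by ascending centroid value at the
    final time point, then by original label.  A pure function of the
    centroid matrix, so relabeling the input clusters cannot change the
    resulting assignment.
    """
    peak = centroids.argmax(axis=1)
    final = centroids[:, -1]
    labels = np.arange(len(centroids))
    return np.lexsort((labels, final, peak))


class TemporalModuleKMeans(ClusterMixin, BaseEstimator):
    """Seeded kmeans over relative profiles with peak-time DG ordering.

    Fitted attributes: ``labels_`` (DG index 1..K per profile),
    ``cluster_centers_`` (K × T, row i is DG i+1), ``phases_`` (DG → phase
    label, or None when no map applies), ``inertia_``.
    """

    def __init__(self, n_clusters: int = 10, n_init: int = 100,
                 random_state: int | None = None, phase_map: dict | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state
        self.phase_map = phase_map

    def _phases(self):
        pm = self.phase_map
        if pm is None:
            pm = DEFAULT_PHASE_MAP if self.n_clusters == 10 else None
        if pm is None:
            return None
        if set(pm) != set(range(1, self.n_clusters + 1)):
            raise ConfigurationError(
                f"phase map keys {sorted(pm)} incompatible with k={self.n_clusters}")
        bad = set(pm.values()) - set(PHASES)
        if bad:
            raise ConfigurationError(f"unknown phase labels {sorted(bad)}")
        return dict(pm)

    def fit(self, X, y=None):
        values = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if len(values) < self.n_clusters:
            raise ConfigurationError(
                f"k={self.n_clusters} exceeds the {len(values)} profiles")
        phases = self._phases()
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                    random_state=self.random_state)
        raw = km.fit_predict(values)
        order = _dg_order(km.cluster_centers_)
        dg_of_raw = np.empty(self.n_clusters, dtype=int)
        dg_of_raw[order] = np.arange(1, self.n_clusters + 1)
        self.labels_ = dg_of_raw[raw]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.inertia_ = float(km.inertia_)
        self.phases_ = phases
        return self

    def assignments(self, index=None) -> pd.DataFrame:
        """DG assignment frame (gene_id, dg, phase) for the fitted profiles."""
        idx = pd.Index(index if index is not None else range(len(self.labels_)),
                       name="gene_id")
        out = pd.DataFrame({"dg": self.labels_}, index=idx)
        out["phase"] = ([self.phases_[d] for d in self.labels_]
                        if self.phases_ is not None else None)
        return out


def fit_clusters(profiles: pd.DataFrame, k: int = 10, seed: int | None = None,
                 n_init: int = 100) -> TemporalModuleKMeans:
    """Fit the temporal-module model on a profile frame."""
    return TemporalModuleKMeans(n_clusters=k, n_init=n_init,
                                random_state=seed).fit(profiles)


def order_dgs(model: TemporalModuleKMeans, profiles: pd.DataFrame):
    """(DG assignments, ordered centroid table) for a fitted model."""
    assignments = model.assignments(profiles.index)
    centroids = pd.DataFrame(model.cluster_centers_,
                             index=pd.RangeIndex(1, model.n_clusters + 1, name="dg"),
                             columns=profiles.columns)
    return assignments, centroids


def heatmap_matrix(assignments: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Profiles reordered for display: by DG, then gene peak time, then gene id.

    Values are the relative profiles untouched; the row order is canonical,
    so shuffled inputs produce identical output.
    """
    missing = assignments.index.difference(profiles.index)
    if len(missing):
        raise ValidationError(f"assignments cover genes without profiles: {list(missing[:3])}")
    sub = profiles.loc[assignments.index]
    peak = sub.to_numpy(float).argmax(axis=1)
    order = np.lexsort((sub.index.to_numpy(), peak, assignments["dg"].to_numpy()))
    return sub.iloc[order]
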