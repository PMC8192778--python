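"""Group-wise brain-state identification.

Windowed correlation matrices from all subjects of one group are vectorized
(strict lower triangle, optionally Fisher z-transformed) and clustered with
k-means.  The number of states k is selected by the maximal mean silhouette
coefficient over a range of candidate k, with ties broken toward smaller k.
Each group is clustered separately, so state repertoires (including k) may
differ between groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import ClusteringError, ParameterError, ValidationError

_Z_CLIP = 1.0 - 1e-7


def pair_labels(network_names) -> list:
    """Strict-lower-triangle pair labels in row-major (i > j) order."""
    names = list(network_names)
    return [f"{names[i]}-{names[j]}" for i in range(len(names)) for j in range(i)]


def vectorize_matrix(corr: np.ndarray) -> np.ndarray:
    """Strict lower triangle of a square matrix, row-major (i > j) order."""
    corr = np.asarray(corr)
    i, j = np.tril_indices(corr.shape[0], k=-1)
    return corr[i, j]


def devectorize(vec: np.ndarray, n_networks: int) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix` (unit diagonal restored)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_networks * (n_networks - 1) // 2:
        raise ValidationError("vector length does not match n_networks")
    out = np.eye(n_networks)
    i, j = np.tril_indices(n_networks, k=-1)
    out[i, j] = vec
    out[j, i] = vec
    return out


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped away from 1 to keep z finite."""
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def vectorize_connectivity(conns, use_fisher_z: bool = True) -> pd.DataFrame:
    """Stack windowed connectivity into a (subject, window) x pair frame.

    Rows follow the order of ``conns`` (manifest order) with windows in time
    order inside each subject; the row index is (subject_id, window_onset).
    """
    conns = list(conns)
    if not conns:
        raise ValidationError("no connectivity provided")
    names = conns[0].network_names
    for wc in conns:
        if wc.network_names != names:
            raise ValidationError(
                f"inconsistent network ordering for subject {wc.subject_id!r}"
            )
    i, j = np.tril_indices(len(names), k=-1)
    blocks, index = [], []
    for wc in conns:
        blocks.append(wc.matrices[:, i, j])
        index.extend((wc.subject_id, int(on)) for on in wc.window_onsets)
    values = np.vstack(blocks)
    if use_fisher_z:
        values = fisher_z(values)
    return pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(index, names=["subject_id", "window_onset"]),
        columns=pair_labels(names),
    )


class BrainStateClustering(ClusterMixin, BaseEstimator):
    """k-means brain-state model with silhouette selection of k.

    For each candidate k the best of ``n_restarts`` seeded k-means fits (by
    within-cluster sum of squares) is kept; the chosen k maximizes the mean
    silhouette coefficient, ties broken toward smaller k.  A fit whose best
    silhouette falls below ``one_state_threshold`` is flagged as effectively
    one-state (silhouette cannot select k=1 directly).

    Attributes
    ----------
    k_ : int
        Selected number of states.
    cluster_centers_ : ndarray of shape (k, n_pairs)
    labels_ : ndarray
        0-based state label per training row.
    silhouette_ : float
        Mean silhouette at the selected k.
    silhouette_by_k_ : dict
        Candidate k -> best mean silhouette.
    one_state_flag_ : bool
    """

    def __init__(self, k_range=(2, 8), n_restarts: int = 50,
                 random_state: int | None = 0,
                 silhouette_subsample: int | None = None,
                 one_state_threshold: float = 0.25):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.silhouette_subsample = silhouette_subsample
        self.one_state_threshold = one_state_threshold

    def _seed(self, offset: int) -> int:
        base = 0 if self.random_state is None else int(self.random_state)
        return (base + 1_000_003 * (offset + 1)) % (2**31 - 1)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D (rows = windows)")
        k_min, k_max = int(self.k_range[0]), int(self.k_range[1])
        if k_min < 2:
            raise ParameterError("k_min must be >= 2 (silhouette undefined at k=1)")
        n_distinct = np.unique(X, axis=0).shape[0]
        k_max = min(k_max, n_distinct - 1, X.shape[0] - 1)
        if k_max < k_min:
            raise ClusteringError(
                f"too few distinct rows ({n_distinct}) for k_min={k_min}"
            )
        best = None
        self.silhouette_by_k_ = {}
        for k in range(k_min, k_max + 1):
            km = KMeans(n_clusters=k, n_init=self.n_restarts,
                        random_state=self._seed(k))
            labels = km.fit_predict(X)
            if len(np.unique(labels)) < k:
                raise ClusteringError(f"empty cluster at k={k} after restarts")
            sil = self._silhouette(X, labels)
            self.silhouette_by_k_[k] = sil
            if best is None or sil > best[0] + 1e-12:
                best = (sil, k, km)
        sil, k, km = best
        self.k_ = k
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = km.inertia_
        self.silhouette_ = sil
        self.one_state_flag_ = sil < self.one_state_threshold
        self.n_features_in_ = X.shape[1]
        return self

    def _silhouette(self, X, labels) -> float:
        n = X.shape[0]
        sub = self.silhouette_subsample
        if sub is not None and sub < n:
            rng = np.random.default_rng(self._seed(0))
            idx = rng.choice(n, size=sub, replace=False)
            Xs, ls = X[idx], labels[idx]
            if len(np.unique(ls)) < 2:  # degenerate subsample; fall back
                Xs, ls = X, labels
        else:
            Xs, ls = X, labels
        return float(silhouette_score(Xs, ls))

    def predict(self, X):
        """Nearest-centroid state assignment (ties to the lower state id)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValidationError(
                f"feature dimension {X.shape[1]} does not match centroids "
                f"({self.cluster_centers_.shape[1]})"
            )
        d = np.linalg.norm(X[:, None, :] - self.cluster_centers_[None, :, :], axis=2)
        # round distances to break floating-point asymmetries in exact ties
        return np.argmin(np.round(d, 12), axis=1)


@dataclass
class StateModel:
    """A group's fitted state repertoire (1-based state ids)."""

    group: str
    k: int
    centroids: np.ndarray
    labels: pd.Series  # index (subject_id, window_onset), values 1..k
    silhouette: float
    silhouette_by_k: dict
    one_state_flag: bool
    estimator: BrainStateClustering


def fit_group_states(features: pd.DataFrame, k_range=(2, 8), n_restarts: int = 50,
                     seed: int | None = 0, group: str = "",
                     silhouette_subsample: int | None = None) -> StateModel:
    """Fit one group's brain states; callers fit ASD and TD separately."""
    est = BrainStateClustering(k_range=k_range, n_restarts=n_restarts,
                               random_state=seed,
                               silhouette_subsample=silhouette_subsample)
    est.fit(features.to_numpy())
    labels = pd.Series(est.labels_ + 1, index=features.index, name="state")
    return StateModel(group=group, k=est.k_, centroids=est.cluster_centers_,
                      labels=labels, silhouette=est.silhouette_,
                      silhouette_by_k=dict(est.silhouette_by_k_),
                      one_state_flag=est.one_state_flag_, estimator=est)


def assign_states(model: StateModel, features: pd.DataFrame) -> pd.Series:
    """Label rows of ``features`` with the nearest centroid (1-based)."""
    pred = model.estimator.predict(features.to_numpy())
    return pd.Series(pred + 1, index=features.index, name="state")
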