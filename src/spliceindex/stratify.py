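"""Severity stratification of SI scores.

Two routes: the fixed published thresholds (Mild 0-0.4, Moderate
0.4-0.75, Severe 0.75-1.0, boundaries inclusive in the lower stratum) and
a data-driven 1-D k-means whose per-cluster min/max define empirical
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = ["Stratum", "StrataBounds", "stratify_fixed", "KMeansStratifier", "kmeans_strata"]


class Stratum(str, Enum):
    MILD = "Mild"
    MODERATE = "Moderate"
    SEVERE = "Severe"


_STRATUM_ORDER = [Stratum.MILD, Stratum.MODERATE, Stratum.SEVERE]


def stratify_fixed(si: float) -> Stratum:
    """Fixed-threshold stratum: 0 <= SI <= 0.4 Mild, 0.4 < SI <= 0.75
    Moderate, 0.75 < SI <= 1.0 Severe."""
    if not 0.0 <= si <= 1.0:
        raise ValueError(f"SI {si} outside [0, 1]")
    if si <= 0.4:
        return Stratum.MILD
    if si <= 0.75:
        return Stratum.MODERATE
    return Stratum.SEVERE


@dataclass
class StrataBounds:
    """Per-cluster (min, max) SI spans, ordered by ascending center."""

    bounds: list[tuple[float, float]]
    centers: list[float]
    labels: np.ndarray  # cluster index per sample, ordered by center


class KMeansStratifier(BaseEstimator):
    """1-D k-means over SI scores with restarts; clusters are relabeled by
    ascending center so cluster 0 is always the mildest.

    If the data hold fewer distinct values than ``k``, k is reduced with a
    warning (documented degenerate behavior).
    """

    def __init__(self, k: int = 3, restarts: int = 50, seed: int | None = None):
        self.k = k
        self.restarts = restarts
        self.seed = seed

    def fit(self, X, y=None) -> "KMeansStratifier":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < self.k:
            raise ValueError(f"need at least k={self.k} samples, got {x.size}")
        k = self.k
        n_unique = np.unique(x).size
        if n_unique < k:
            warnings.warn(
                f"only {n_unique} distinct values; reducing k from {k} to {n_unique}",
                stacklevel=2,
            )
            k = n_unique
        km = KMeans(n_clusters=k, n_init=self.restarts, random_state=self.seed).fit(
            x.reshape(-1, 1)
        )
        order = np.argsort(km.cluster_centers_.ravel())
        remap = np.empty_like(order)
        remap[order] = np.arange(k)
        labels = remap[km.labels_]
        self.n_clusters_ = k
        self.centers_ = [float(km.cluster_centers_.ravel()[i]) for i in order]
        self.bounds_ = [
            (float(x[labels == j].min()), float(x[labels == j].max())) for j in range(k)
        ]
        self.labels_ = labels
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "centers_")
        x = np.asarray(X, dtype=float).ravel()
        centers = np.asarray(self.centers_)
        return np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)

    def strata(self) -> list[Stratum]:
        """Map ordered clusters onto Mild/Moderate/Severe (k == 3 only)."""
        check_is_fitted(self, "centers_")
        if self.n_clusters_ != 3:
            raise ValueError("stratum names are defined for k=3")
        return [_STRATUM_ORDER[j] for j in self.labels_]


def kmeans_strata(
    si_values, k: int = 3, restarts: int = 50, seed: int | None = None
) -> StrataBounds:
    """Cluster SI scores and return per-cluster bounds and assignments."""
    est = KMeansStratifier(k=k, restarts=restarts, seed=seed).fit(si_values)
    return StrataBounds(bounds=est.bounds_, centers=est.centers_, labels=est.labels_)
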