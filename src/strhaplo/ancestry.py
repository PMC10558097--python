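"""Ancestry assignment by distance-to-reference-group thresholding.

Samples are projected onto a principal-component space (the projection is
a plain linear map with supplied loadings; computing loadings is out of
scope) and compared with reference-group centroids.  Squared Euclidean
distance is converted to an approximate fixation index (FST) by a linear
scale supplied with the reference set; a sample is assigned to its nearest
group only when that approximate FST falls strictly below the threshold
(default 0.002), otherwise it is left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .loci import InvalidParameterError

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AncestryAssignment:
    sample: str
    fst_by_group: dict[str, float]
    assigned: str  # group label or "unassigned"

    @property
    def best_group(self) -> str:
        return min(self.fst_by_group, key=lambda g: (self.fst_by_group[g], g))

    @property
    def best_fst(self) -> float:
        return self.fst_by_group[self.best_group]


def dist_to_fst(d2: float | np.ndarray, scale: float) -> float | np.ndarray:
    """Convert squared Euclidean PC-space distance to approximate FST.

    A strictly increasing linear map through the origin: fst = d2 / scale.
    """
    if scale <= 0:
        raise InvalidParameterError("scale must be positive")
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise InvalidParameterError("squared distances must be >= 0")
    out = d2 / scale
    return float(out) if out.ndim == 0 else out


class AncestryClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-centroid ancestry classifier with an FST acceptance gate.

    Fit on reference-group centroids (one row per group) with their
    labels; ``predict`` returns the nearest group's label when its
    approximate FST is strictly below ``threshold``, else "unassigned".
    Argmin ties break lexicographically by label.
    """

    def __init__(self, threshold: float = 0.002, scale: float = 1.0):
        self.threshold = threshold
        self.scale = scale

    def fit(self, X: np.ndarray, y) -> "AncestryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise InvalidParameterError("need one centroid row per label")
        if not np.all(np.isfinite(X)):
            raise InvalidParameterError("centroids must be finite")
        order = np.argsort(y.astype(str))  # lexicographic tie-break via order
        self.classes_ = y[order]
        self.centroids_ = X[order]
        self.n_features_in_ = X.shape[1]
        return self

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise InvalidParameterError(
                f"expected {self.n_features_in_} coordinates, "
                f"got {X.shape[1]}")
        return X

    def predict_fst(self, X: np.ndarray) -> np.ndarray:
        """Approximate FST from each sample to every reference group."""
        X = self._check(X)
        return dist_to_fst(cdist(X, self.centroids_, "sqeuclidean"),
                           self.scale)

    def predict(self, X: np.ndarray) -> np.ndarray:
        fst = self.predict_fst(X)
        best = fst.argmin(axis=1)  # classes_ sorted, argmin takes first tie
        labels = self.classes_[best].astype(object)
        labels[fst[np.arange(len(best)), best] >= self.threshold] = UNASSIGNED
        return labels


def assign(sample_coords: np.ndarray, centroids: np.ndarray,
           labels, scale: float, threshold: float = 0.002,
           sample: str = "sample") -> AncestryAssignment:
    """Assign one sample; functional wrapper over AncestryClassifier."""
    clf = AncestryClassifier(threshold=threshold, scale=scale)
    clf.fit(centroids, labels)
    fst = clf.predict_fst(sample_coords)[0]
    return AncestryAssignment(
        sample=sample,
        fst_by_group={str(g): float(f) for g, f in zip(clf.classes_, fst)},
        assigned=str(clf.predict(sample_coords)[0]))
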