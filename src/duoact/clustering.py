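"""Time clustering of activities and elbow-method selection of k.

Daily activities of elderly residents are temporally regular, so the
(begin-hour, end-hour) pairs of activity instances form natural clusters
(morning, noon, evening ...).  k-means partitions the instances in that
2-D hour space; the cluster count k is chosen at the elbow of the
SSE-vs-k curve, operationalised as the k with the largest discrete
curvature (second difference) of SSE(k).

Both axes are hours on the same 0-23 range, so points enter k-means
unscaled, and hour differences are linear (not circular).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "kmeans", "sse", "select_k", "sse_curve"]

TimePoint = tuple[float, float]  # (begin hour, end hour)


@dataclass(frozen=True)
class ClusterModel:
    """A fitted k-means partition of (bt, et) points.

    ``centroids`` has shape (k, 2) with fractional hours allowed;
    ``assignment[i]`` is the cluster index of training point i; ``sse``
    is the total within-cluster sum of squared Euclidean distances.
    """

    k: int
    centroids: np.ndarray
    assignment: np.ndarray
    sse: float

    def predict(self, point: TimePoint) -> int:
        """Index of the centroid nearest (Euclidean) to ``point``."""
        p = np.asarray(point, dtype=float)
        return int(np.argmin(((self.centroids - p) ** 2).sum(axis=1)))


def _as_array(points: Sequence[TimePoint]) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"points must be (n, 2) (bt, et) pairs, got shape {arr.shape}")
    return arr


def kmeans(points: Sequence[TimePoint], k: int, seed: int = 0) -> ClusterModel:
    """Fit k-means (k-means++ init, 10 restarts, Lloyd) on (bt, et) points.

    Deterministic given ``(points, k, seed)``.

    Raises
    ------
    ValueError
        If ``k < 1`` or ``k`` exceeds the number of distinct points.
    """
    arr = _as_array(points)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_distinct = len(np.unique(arr, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct points ({n_distinct})")
    est = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        algorithm="lloyd",
        random_state=seed,
    ).fit(arr)
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_.copy(),
        assignment=est.labels_.copy(),
        sse=float(est.inertia_),
    )


def sse(points: Sequence[TimePoint], model: ClusterModel) -> float:
    """Sum of squared Euclidean distances of each point to its centroid."""
    arr = _as_array(points)
    if len(arr) != len(model.assignment):
        raise ValueError("model does not assign every point")
    diffs = arr - model.centroids[model.assignment]
    return float((diffs**2).sum())


def sse_curve(
    points: Sequence[TimePoint], k_max: int, seed: int = 0
) -> list[tuple[int, float]]:
    """Best-of-restarts SSE for k = 1 .. k_max, as (k, SSE) pairs."""
    return [(k, kmeans(points, k, seed=seed).sse) for k in range(1, k_max + 1)]


def select_k(
    points: Sequence[TimePoint],
    num_classes: int,
    seed: int = 0,
    method: Literal["curvature", "kneedle"] = "curvature",
) -> int:
    """Choose the cluster count k by the elbow of the SSE-vs-k curve.

    SSE(k) is computed for k = 1 .. ``num_classes``.  With the default
    ``"curvature"`` method the returned k maximises the discrete
    curvature |y''| / (1 + y'^2)^(3/2) of the min-max-normalised SSE
    curve over interior k in [2, num_classes - 1], with y'' the second
    difference SSE(k-1) - 2·SSE(k) + SSE(k+1) and y' the central first
    difference.  Normalising both axes before taking the curvature is
    what makes the elbow (not the steep initial drop) the maximum.
    ``"kneedle"`` instead maximises the vertical distance of the
    normalised SSE curve below the straight line joining its endpoints.
    Ties go to the smaller k.

    Parameters
    ----------
    num_classes
        Upper bound of the scan — the number of activity classes.
        Must be >= 3 so the curvature at an interior k is defined.
    """
    if num_classes < 3:
        raise ValueError(f"num_classes must be >= 3, got {num_classes}")
    arr = _as_array(points)
    n_distinct = len(np.unique(arr, axis=0))
    k_max = num_classes
    if n_distinct < k_max:
        warnings.warn(
            f"only {n_distinct} distinct points; reducing elbow scan upper "
            f"bound from {k_max} to {n_distinct}",
            stacklevel=2,
        )
        k_max = n_distinct
        if k_max < 3:
            return max(1, k_max)
    curve = np.array([s for _, s in sse_curve(points, k_max, seed=seed)])
    ks = np.arange(1, k_max + 1)
    if method == "curvature":
        span = curve.max() - curve.min()
        if span <= 0:  # flat curve: no elbow, smallest interior k
            return 2
        y = (curve - curve.min()) / span
        h = 1.0 / (k_max - 1)  # k axis normalised to [0, 1]
        ypp = (y[:-2] - 2.0 * y[1:-1] + y[2:]) / h**2
        yp = (y[2:] - y[:-2]) / (2.0 * h)
        scores = np.abs(ypp) / (1.0 + yp**2) ** 1.5
        best = int(np.argmax(scores))
        return int(ks[1:-1][best])
    if method == "kneedle":
        s = (curve - curve.min()) / (curve.max() - curve.min() + 1e-300)
        x = (ks - ks[0]) / (ks[-1] - ks[0])
        chord = s[0] + (s[-1] - s[0]) * x
        best = int(np.argmax(chord - s))
        return int(ks[best])
    raise ValueError(f"unknown method {method!r}")
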