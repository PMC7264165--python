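"""K-means spatial clustering of maxima coordinates with automatic
selection of k by the elbow criterion.

The classification is purely spatial: band-pair labels are carried
through but never inform the partition.  k-means (Lloyd iterations from
k-means++ initializations, best of many restarts) is run for every
k = 1..n; the within-cluster sum of squares SSW(k) forms the elbow
curve, and the selected k is the point whose discrete tangent is most
parallel to the chord joining the curve's first and last points.

The Lloyd loop is implemented here rather than delegated so that the
per-iteration SSW monotonicity contract can be asserted and the restart/
relabeling behavior is fully deterministic; scikit-learn's KMeans serves
as an independent cross-check in the test-suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KMeansFit",
    "ElbowCurve",
    "ClusterSolution",
    "kmeans",
    "ssw_curve",
    "elbow_select",
    "cluster_points",
]


@dataclass
class KMeansFit:
    """Best-of-restarts Lloyd solution with deterministic labeling.

    Labels are 1..k; clusters are numbered by descending size, ties
    broken by lexicographic centroid order.  ``ssw_history`` is the
    per-iteration SSW trace of the winning restart (non-increasing).
    """

    labels: np.ndarray
    centroids: np.ndarray
    ssw: float
    n_restarts: int
    ssw_history: np.ndarray

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers[c] = x[rng.integers(n)]
            continue
        centers[c] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centers[c]) ** 2).sum(1))
    return centers


def _lloyd(
    x: np.ndarray, centers: np.ndarray, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = len(centers)
    history: list[float] = []
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(1)
        ssw = float(d2[np.arange(len(x)), labels].sum())
        if history and ssw > history[-1] + 1e-9 * max(1.0, history[-1]):
            raise AssertionError("Lloyd iteration increased SSW")
        converged = bool(history) and history[-1] - ssw <= 1e-12 * max(1.0, ssw)
        history.append(ssw)
        new_centers = centers.copy()
        for c in range(k):
            members = x[labels == c]
            if len(members):
                new_centers[c] = members.mean(0)
            else:  # re-seed an empty cluster at the farthest point
                far = d2.min(1).argmax()
                new_centers[c] = x[far]
                converged = False
        if converged and np.allclose(new_centers, centers):
            break
        centers = new_centers
    return labels, centers, history[-1], history


def _relabel(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic cluster numbering: descending size, then lexicographic
    centroid; returned labels are 1-based."""
    k = len(centroids)
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], tuple(centroids[c])))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels], centroids[order]


def kmeans(
    points: np.ndarray,
    k: int,
    n_restarts: int = 200,
    rng: "np.random.Generator | int | None" = 0,
) -> KMeansFit:
    """Best of ``n_restarts`` Lloyd runs from k-means++ initializations."""
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("points must be a 2-D array (n x dim)")
    if not np.isfinite(x).all():
        raise ValueError("points must be finite")
    if not (1 <= k <= len(x)):
        raise ValueError(f"k must satisfy 1 <= k <= n (= {len(x)}), got {k}")
    rng = np.random.default_rng(rng)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        labels, centers, ssw, history = _lloyd(x, _kmeanspp_init(x, k, rng), rng)
        if best is None or ssw < best[0]:
            best = (ssw, labels, centers, history)
    ssw, labels, centers, history = best
    labels, centers = _relabel(labels, centers)
    return KMeansFit(
        labels=labels,
        centroids=centers,
        ssw=ssw,
        n_restarts=n_restarts,
        ssw_history=np.asarray(history),
    )


@dataclass
class ElbowCurve:
    """SSW as a function of k = 1..n, isotonically repaired."""

    ssw: np.ndarray  # index k-1 holds SSW(k)

    def __post_init__(self) -> None:
        self.ssw = np.asarray(self.ssw, dtype=float)

    @property
    def n(self) -> int:
        return len(self.ssw)


def ssw_curve(
    points: np.ndarray,
    n_restarts: int = 200,
    rng: "np.random.Generator | int | None" = 0,
) -> ElbowCurve:
    """SSW(k) for every k = 1..n, best of restarts per k.

    A restart artifact can leave SSW(k+1) > SSW(k); the curve is repaired
    to be non-increasing (running minimum), which a globally optimal
    curve satisfies by nesting of the feasible partitions.
    """
    x = np.asarray(points, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points for an SSW curve")
    rng = np.random.default_rng(rng)
    ssw = np.array(
        [kmeans(x, k, n_restarts=n_restarts, rng=rng).ssw for k in range(1, len(x) + 1)]
    )
    return ElbowCurve(ssw=np.minimum.accumulate(ssw))


def elbow_select(curve: ElbowCurve) -> tuple[int, bool]:
    """k whose discrete tangent is most parallel to the first-to-last chord.

    The tangent at interior k is the central difference
    (SSW(k+1) - SSW(k-1)) / 2; one-sided differences are used at the
    ends.  Ties take the smallest k.  A flat curve returns (1, True)
    with the degenerate flag set.
    """
    y = curve.ssw
    n = len(y)
    if n < 3:
        raise ValueError("elbow selection needs a curve of length >= 3")
    if np.allclose(y, y[0]):
        return 1, True
    chord = (y[-1] - y[0]) / (n - 1)
    tangent = np.empty(n)
    tangent[0] = y[1] - y[0]
    tangent[-1] = y[-1] - y[-2]
    tangent[1:-1] = (y[2:] - y[:-2]) / 2.0
    return int(np.argmin(np.abs(tangent - chord))) + 1, False


@dataclass
class ClusterSolution:
    """Elbow-selected k-means partition of a set of 3-D maxima coordinates."""

    selected_k: int
    labels: np.ndarray  # 1..k per point
    centroids: np.ndarray
    ssw: float
    curve: ElbowCurve
    degenerate: bool = False
    n_restarts: int = 200
    band_pairs: list[tuple[str, str]] | None = field(default=None)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.selected_k + 1)[1:]


def cluster_points(
    points: np.ndarray,
    n_restarts: int = 200,
    rng: "np.random.Generator | int | None" = 0,
    band_pairs: list[tuple[str, str]] | None = None,
) -> ClusterSolution:
    """Full elbow analysis: SSW curve, k selection, final partition."""
    x = np.asarray(points, dtype=float)
    rng = np.random.default_rng(rng)
    curve = ssw_curve(x, n_restarts=n_restarts, rng=rng)
    k, degenerate = elbow_select(curve)
    fit = kmeans(x, k, n_restarts=n_restarts, rng=rng)
    return ClusterSolution(
        selected_k=k,
        labels=fit.labels,
        centroids=fit.centroids,
        ssw=fit.ssw,
        curve=curve,
        degenerate=degenerate,
        n_restarts=n_restarts,
        band_pairs=band_pairs,
    )
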