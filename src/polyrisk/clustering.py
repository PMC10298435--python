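"""Flat-kernel mean-shift clustering of risk profiles.

Mean shift is a density-based mode-seeking method: every data point is a
seed that iteratively moves to the arithmetic mean of all points within one
bandwidth of it, and converged seeds that land within a bandwidth of each
other merge into a single cluster centre.  The cluster count therefore
emerges from the data instead of being preset, which suits risk
stratification: rare extreme-score patients form their own small,
high-mean clusters that can be surfaced for medication review.

The bandwidth is estimated from the pairwise-distance structure of the data:
with ``k = max(1, floor(n * quantile))``, it is the mean over all points of
the distance to their k-th nearest neighbour (self included).  The default
quantile is 0.3.

Because risk scores are small integers, cohorts contain massive numbers of
duplicated coordinates.  Identical seeds follow identical trajectories under
the flat-kernel update, so the implementation collapses duplicates into
weighted unique points — an exact optimisation that makes the procedure
linear in the number of *distinct* score vectors per iteration.

Clusters are then ranked into risk groups (rank 1 = highest mean risk) and
colour-tiered red/amber/green for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

_CHUNK = 512  # row block for pairwise-distance computations


def _as_points(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D array of points, got shape {X.shape}")
    if X.shape[0] == 0:
        raise ValueError("at least one point is required")
    if not np.isfinite(X).all():
        raise ValueError("points must be finite")
    return X


def estimate_bandwidth(X, quantile: float = 0.3) -> float:
    """Quantile-based kernel bandwidth.

    For each of the n points, take the Euclidean distance to its k-th
    nearest neighbour among all points *including itself*, with
    ``k = max(1, floor(n * quantile))``; return the mean of these n
    distances.  Deterministic; returns 0.0 when k = 1 or when all points
    coincide (callers must engage the degenerate-bandwidth fallback).
    """
    X = _as_points(X)
    if not 0.0 < quantile <= 1.0:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    n = X.shape[0]
    k = max(1, math.floor(n * quantile))
    kth = np.empty(n)
    for start in range(0, n, _CHUNK):
        block = slice(start, min(start + _CHUNK, n))
        d = cdist(X[block], X)
        kth[block] = np.partition(d, k - 1, axis=1)[:, k - 1]
    return float(kth.mean())


def max_pairwise_distance(X) -> float:
    X = _as_points(X)
    best = 0.0
    for start in range(0, X.shape[0], _CHUNK):
        d = cdist(X[start:start + _CHUNK], X)
        best = max(best, float(d.max()))
    return best


def _flat_mean_shift(
    X: np.ndarray,
    bandwidth: float,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run the flat-kernel mean-shift procedure.

    Returns (centers, labels, n_iter).  Duplicate rows are collapsed into
    weighted unique points; every unique point is a seed.  A seed stops when
    its displacement falls below ``tol * bandwidth``.  Converged modes are
    merged: modes are sorted by within-bandwidth support (descending, ties
    broken by lexicographic coordinate order) and a mode is kept iff no
    already-kept mode lies within one bandwidth of it.  Every point is
    labelled with its nearest kept centre, so the labels partition the data.
    """
    unique, counts = np.unique(X, axis=0, return_counts=True)
    modes = unique.astype(float).copy()
    weights = counts.astype(float)
    tol_abs = tol * bandwidth
    converged = np.zeros(len(modes), dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        live = ~converged
        if not live.any():
            n_iter -= 1
            break
        d = cdist(modes[live], unique)
        within = d <= bandwidth
        w = within * weights  # flat kernel, weighted by duplicate multiplicity
        shifted = (w @ unique) / w.sum(axis=1, keepdims=True)
        displacement = np.linalg.norm(shifted - modes[live], axis=1)
        modes[live] = shifted
        idx = np.flatnonzero(live)
        converged[idx[displacement < tol_abs]] = True

    # Mode merging: support-sorted greedy suppression within one bandwidth.
    d_support = cdist(modes, unique)
    support = ((d_support <= bandwidth) * weights).sum(axis=1)
    order = sorted(range(len(modes)), key=lambda i: (-support[i], tuple(modes[i])))
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(modes[i] - modes[j]) > bandwidth for j in kept):
            kept.append(i)
    centers = modes[kept]
    labels = np.argmin(cdist(X, centers), axis=1)
    return centers, labels, n_iter


class QuantileMeanShift:
    """Mean-shift clusterer with quantile-estimated bandwidth.

    Follows the scikit-learn estimator protocol (``get_params`` /
    ``set_params`` / ``fit`` / ``fit_predict`` / ``predict``, fitted
    attributes with a trailing underscore) so it composes with sklearn
    pipelines and model selection, while the algorithm itself is implemented
    here from first principles.

    Parameters
    ----------
    bandwidth : float, optional
        Kernel radius in feature units.  Estimated from ``quantile`` when
        not given.
    quantile : float, default 0.3
        Pairwise-distance quantile used by :func:`estimate_bandwidth`.
    max_iter : int, default 300
        Iteration cap per seed.
    tol : float, default 1e-3
        A seed converges when its displacement drops below
        ``tol * bandwidth``.
    min_bandwidth_factor : float, default 1e-3
        Degenerate-bandwidth fallback: when the estimate is 0 (heavy integer
        ties make this common), substitute this fraction of the maximum
        pairwise distance.  If that is also 0 every point coincides and the
        data form a single cluster.

    Attributes
    ----------
    bandwidth_ : float
        Bandwidth actually used (post-fallback; 0.0 only when all points
        coincide).
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    labels_ : ndarray of shape (n_samples,)
    n_iter_ : int
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        quantile: float = 0.3,
        max_iter: int = 300,
        tol: float = 1e-3,
        min_bandwidth_factor: float = 1e-3,
    ) -> None:
        self.bandwidth = bandwidth
        self.quantile = quantile
        self.max_iter = max_iter
        self.tol = tol
        self.min_bandwidth_factor = min_bandwidth_factor

    # -- sklearn protocol ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "bandwidth": self.bandwidth,
            "quantile": self.quantile,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "min_bandwidth_factor": self.min_bandwidth_factor,
        }

    def set_params(self, **params) -> "QuantileMeanShift":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for QuantileMeanShift")
            setattr(self, key, value)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None) -> "QuantileMeanShift":
        X = _as_points(X)
        if self.bandwidth is not None:
            if self.bandwidth <= 0:
                raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")
            bandwidth = float(self.bandwidth)
        else:
            bandwidth = estimate_bandwidth(X, self.quantile)
        if bandwidth == 0.0:
            bandwidth = self.min_bandwidth_factor * max_pairwise_distance(X)
        if bandwidth == 0.0:
            # All points coincide: a single trivial cluster.
            self.bandwidth_ = 0.0
            self.cluster_centers_ = X[:1].copy()
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            self.n_iter_ = 0
        else:
            centers, labels, n_iter = _flat_mean_shift(X, bandwidth, self.max_iter, self.tol)
            self.bandwidth_ = bandwidth
            self.cluster_centers_ = centers
            self.labels_ = labels
            self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("QuantileMeanShift instance is not fitted yet")
        X = _as_points(X)
        return np.argmin(cdist(X, self.cluster_centers_), axis=1)


def mean_shift(X, bandwidth: float, max_iter: int = 300, tol: float = 1e-3):
    """Functional wrapper: (centers, labels) for a given positive bandwidth."""
    model = QuantileMeanShift(bandwidth=bandwidth, max_iter=max_iter, tol=tol).fit(X)
    return model.cluster_centers_, model.labels_


# -- risk grouping ----------------------------------------------------------

TIERS = ("red", "amber", "green")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-patient feature vectors (1-D WARS or WIRS, or 2-D joint)."""

    patient_ids: tuple[str, ...]
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        points = _as_points(self.points)
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        if len(self.patient_ids) != points.shape[0]:
            raise ValueError("one feature vector per patient required")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids in feature matrix")
        if points.shape[1] not in (1, 2):
            raise ValueError("features must be 1-D or 2-D")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class RiskGroup:
    """One ranked cluster: rank 1 is the highest-risk group."""

    rank: int
    size: int
    mean_risk: tuple[float, ...]
    score_range: tuple[tuple[float, float], ...]  # per-feature (min, max)
    center: tuple[float, ...]
    tier: str | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("a risk group has at least one patient")
        for (lo, hi), mean in zip(self.score_range, self.mean_risk):
            if not lo <= mean <= hi:
                raise ValueError("group mean must lie within its score range")


@dataclass(frozen=True)
class RiskGrouping:
    """Ranked clustering output: a partition of patients into risk groups."""

    bandwidth: float
    patient_ids: tuple[str, ...]
    labels: tuple[int, ...]  # 1-based group rank per patient
    groups: tuple[RiskGroup, ...]

    def __post_init__(self) -> None:
        if sum(g.size for g in self.groups) != len(self.patient_ids):
            raise ValueError("group sizes must sum to the number of patients")
        ranks = [g.rank for g in self.groups]
        if ranks != list(range(1, len(self.groups) + 1)):
            raise ValueError("groups must be ranked 1..G")

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _ranking_key(center: np.ndarray, axis_max: np.ndarray) -> float:
    """Ordering key for clusters: the feature mean in 1-D; in 2-D the
    Euclidean norm of the centroid after scaling each axis by its population
    maximum, so neither score's larger range dominates the hierarchy."""
    if center.size == 1:
        return float(center[0])
    return float(np.linalg.norm(center / axis_max))


def rank_clusters(
    features: FeatureMatrix,
    labels: np.ndarray,
    bandwidth: float,
) -> RiskGrouping:
    """Rank raw cluster labels into risk groups, highest mean risk first.

    Per-group statistics (size, per-feature mean and min/max range) are
    computed from the member points; the group "centre" reported is the
    member centroid.  Ties in the ranking key break by centroid coordinates
    (descending) so the ranking is deterministic.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != features.n:
        raise ValueError("one label per patient required")
    axis_max = features.points.max(axis=0)
    axis_max = np.where(axis_max > 0, axis_max, 1.0)
    stats = []
    for cluster in np.unique(labels):
        member = features.points[labels == cluster]
        centroid = member.mean(axis=0)
        stats.append(
            (
                cluster,
                centroid,
                member.shape[0],
                member.min(axis=0),
                member.max(axis=0),
                _ranking_key(centroid, axis_max),
            )
        )
    stats.sort(key=lambda s: (-s[5], tuple(-c for c in s[1])))
    rank_of = {cluster: rank for rank, (cluster, *_rest) in enumerate(stats, start=1)}
    groups = tuple(
        RiskGroup(
            rank=rank,
            size=int(size),
            mean_risk=tuple(float(v) for v in centroid),
            score_range=tuple((float(lo), float(hi)) for lo, hi in zip(mins, maxs)),
            center=tuple(float(v) for v in centroid),
        )
        for rank, (_cluster, centroid, size, mins, maxs, _key) in enumerate(stats, start=1)
    )
    ranked_labels = tuple(int(rank_of[c]) for c in labels)
    return RiskGrouping(
        bandwidth=float(bandwidth),
        patient_ids=features.patient_ids,
        labels=ranked_labels,
        groups=groups,
    )


def assign_tiers(
    grouping: RiskGrouping,
    tier_fractions: tuple[float, float] = (1.0 / 3.0, 1.0 / 3.0),
) -> RiskGrouping:
    """Colour the ranked groups red/amber/green in hierarchical risk order.

    The top ``ceil(f_red * G)`` groups are red, the next
    ``ceil(f_amber * G)`` amber, the remainder green; rank 1 is always red.
    """
    f_red, f_amber = tier_fractions
    if f_red < 0 or f_amber < 0 or f_red + f_amber >= 1.0 + 1e-12:
        raise ValueError("tier fractions must be non-negative and sum to < 1")
    n_groups = grouping.n_groups
    n_red = min(n_groups, math.ceil(f_red * n_groups)) or 1
    n_amber = min(n_groups - n_red, math.ceil(f_amber * n_groups))
    tiered = []
    for group in grouping.groups:
        if group.rank <= n_red:
            tier = "red"
        elif group.rank <= n_red + n_amber:
            tier = "amber"
        else:
            tier = "green"
        tiered.append(replace(group, tier=tier))
    return replace(grouping, groups=tuple(tiered))


def cluster_risk_profiles(
    features: FeatureMatrix,
    quantile: float = 0.3,
    tier_fractions: tuple[float, float] = (1.0 / 3.0, 1.0 / 3.0),
    scale: bool = False,
) -> RiskGrouping:
    """End-to-end grouping: bandwidth -> mean shift -> rank -> tier.

    ``scale`` standardises each feature axis to unit variance before
    clustering (2-D sensitivity switch); ranking statistics are always
    reported on the raw score scale.
    """
    points = features.points
    if scale:
        sd = points.std(axis=0)
        points = points / np.where(sd > 0, sd, 1.0)
    model = QuantileMeanShift(quantile=quantile).fit(points)
    grouping = rank_clusters(features, model.labels_, model.bandwidth_)
    return assign_tiers(grouping, tier_fractions)
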