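"""Unsupervised stage: k-means, Gap statistic, centroid distances, brain age.

PCA-reduced SWA profiles (12 -> 3 dimensions by default) are clustered with
Lloyd's k-means, restarted many times from observation-sampled prototypes
and scored by the within-cluster sum of squares W_k.  The number of clusters
is chosen with the Gap statistic: W_k of the data is compared, on the log
scale, with W_k of reference sets drawn uniformly over the bounding box of
the points, and the k maximizing ``Gap[k] = E[log W_k^ref] - log W_k`` wins.

Pairwise Euclidean distances between per-group centroids summarize how
similar the groups' SWA is.  Taking the young running-wheel group as the
healthy reference, each group's distance to that centroid is a 1-D "brain
age"; the percent reduction of that distance from sedentary control to
running-wheel at a given age quantifies how much exercise attenuates the
apparent brain aging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import ClassLabel

#: Lloyd iteration cap and relative W_k convergence tolerance per restart.
MAX_LLOYD_ITER = 300
LLOYD_TOL = 1e-8

Seed = Union[int, Sequence[int]]


@dataclass
class ClusterSolution:
    """Best-of-restarts k-means solution."""

    k: int
    assignments: np.ndarray  # cluster index per point
    centroids: np.ndarray    # (k, d)
    inertia: float           # W_k: sum of squared distances to own centroid
    restarts: int


def _lloyd(points: np.ndarray, init_idx: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    n = points.shape[0]
    centroids = points[init_idx].astype(float).copy()
    k = centroids.shape[0]
    rows = np.arange(n)
    prev_w = math.inf
    assign = np.zeros(n, dtype=int)
    for _ in range(MAX_LLOYD_ITER):
        d2 = cdist(points, centroids, "sqeuclidean")
        assign = d2.argmin(axis=1)  # argmin ties -> lowest cluster index
        # empty clusters: reseed at the point farthest from its own centroid
        for j in range(k):
            if not np.any(assign == j):
                far = int(d2[rows, assign].argmax())
                centroids[j] = points[far]
                d2[:, j] = ((points - centroids[j]) ** 2).sum(axis=1)
                assign = d2.argmin(axis=1)
        w = float(d2[rows, assign].sum())
        if w > prev_w * (1 + 1e-9) + 1e-12:
            raise AssertionError("within-cluster sum of squares increased during Lloyd iteration")
        converged = prev_w - w <= LLOYD_TOL * max(prev_w, 1e-300)
        prev_w = w
        for j in range(k):
            centroids[j] = points[assign == j].mean(axis=0)
        if converged:
            break
    # final consistency: W against the final centroids
    d2 = cdist(points, centroids, "sqeuclidean")
    assign = d2.argmin(axis=1)
    w = float(d2[rows, assign].sum())
    return assign, centroids, w


def kmeans(
    points: np.ndarray,
    k: int,
    restarts: int = 1000,
    seed: Seed = 0,
) -> ClusterSolution:
    """Lloyd's k-means, best of ``restarts`` seeded runs by W_k.

    Prototypes are sampled without replacement from the observations; empty
    clusters are reseeded from the farthest point; nearest-centroid ties
    break to the lowest cluster index.  Deterministic given the seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n = points.shape[0]
    n_distinct = len(np.unique(points, axis=0))
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k > n_distinct:
        raise ValueError(f"k = {k} exceeds the {n_distinct} distinct points")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, np.ndarray, float]] = None
    for _ in range(restarts):
        init_idx = rng.choice(n, size=k, replace=False)
        assign, centroids, w = _lloyd(points, init_idx)
        if best is None or w < best[2]:
            best = (assign, centroids, w)
    assign, centroids, w = best
    return ClusterSolution(k=k, assignments=assign, centroids=centroids, inertia=w, restarts=restarts)


@dataclass
class GapProfile:
    """Gap-statistic scores over k = 1..k_max and the chosen k*."""

    gap: np.ndarray        # Gap[k], index 0 is k=1
    s: np.ndarray          # reference dispersion spread per k (1-SE scale)
    log_w: np.ndarray      # log W_k of the data
    log_w_ref: np.ndarray  # mean log W_k of the reference sets
    k_star: int
    B: int

    def to_dict(self) -> dict:
        return {
            "k_star": self.k_star,
            "B": self.B,
            "gap": self.gap.tolist(),
            "s": self.s.tolist(),
            "log_w": self.log_w.tolist(),
            "log_w_ref": self.log_w_ref.tolist(),
        }


def gap_statistic(
    points: np.ndarray,
    k_max: int,
    B: int = 100,
    restarts: int = 100,
    ref_restarts: int = 25,
    seed: int = 0,
    one_se: bool = False,
    reference: str = "box",
) -> GapProfile:
    """Select the cluster count by the Gap statistic.

    ``Gap[k] = mean_b log(W_k^(b)) - log(W_k)`` with B reference sets of the
    same size drawn uniformly over the feature-wise bounding box of the
    points (``reference="box"``) or over the box aligned with the data's
    principal axes (``reference="pca_box"``).  By default k* is the global
    maximizer of Gap over k = 1..k_max; ``one_se=True`` instead picks the
    smallest k with ``Gap[k] >= Gap[k+1] - s[k+1]`` where
    ``s = sd(log W^ref) * sqrt(1 + 1/B)``.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if B < 10:
        raise ValueError("B must be >= 10")
    if np.allclose(points, points[0]):
        warnings.warn("all points identical: k* = 1 by convention", stacklevel=2)
        z = np.zeros(1)
        return GapProfile(gap=z, s=z.copy(), log_w=z.copy(), log_w_ref=z.copy(), k_star=1, B=B)
    if not 1 <= k_max <= n - 1:
        raise ValueError(f"k_max must be in [1, {n - 1}]")

    if reference == "box":
        rot = np.eye(d)
        frame = points
    elif reference == "pca_box":
        centered = points - points.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        rot = vt.T  # columns: principal axes
        frame = points @ rot
    else:
        raise ValueError("reference must be 'box' or 'pca_box'")
    lo, hi = frame.min(axis=0), frame.max(axis=0)

    rng_ref = np.random.default_rng([seed, 1])
    refs = [(lo + rng_ref.random((n, d)) * (hi - lo)) @ rot.T for _ in range(B)]

    tiny = 1e-300
    log_w = np.empty(k_max)
    log_w_ref = np.empty((k_max, B))
    for k in range(1, k_max + 1):
        log_w[k - 1] = math.log(max(kmeans(points, k, restarts, seed=[seed, 2, k]).inertia, tiny))
        for b, ref in enumerate(refs):
            sol = kmeans(ref, k, ref_restarts, seed=[seed, 3, k, b])
            log_w_ref[k - 1, b] = math.log(max(sol.inertia, tiny))

    gap = log_w_ref.mean(axis=1) - log_w
    s = log_w_ref.std(axis=1, ddof=1) * math.sqrt(1 + 1 / B)
    if one_se:
        k_star = k_max
        for k in range(1, k_max):
            if gap[k - 1] >= gap[k] - s[k]:
                k_star = k
                break
    else:
        k_star = int(np.argmax(gap)) + 1
    return GapProfile(
        gap=gap, s=s, log_w=log_w, log_w_ref=log_w_ref.mean(axis=1),
        k_star=k_star, B=B,
    )


LabelLike = Union[str, ClassLabel]


@dataclass
class CentroidDistanceMatrix:
    """Symmetric pairwise Euclidean distances between labelled centroids."""

    labels: Tuple[str, ...]
    distances: np.ndarray  # (m, m), zero diagonal

    def distance(self, a: LabelLike, b: LabelLike) -> float:
        ia = self.labels.index(str(a))
        ib = self.labels.index(str(b))
        return float(self.distances[ia, ib])

    def rounded(self, decimals: int = 2) -> np.ndarray:
        return np.round(self.distances, decimals)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "distances": self.distances.tolist()}


def centroid_distances(
    centroids: Union[Mapping[LabelLike, Sequence[float]], Sequence[Tuple[LabelLike, Sequence[float]]]],
) -> CentroidDistanceMatrix:
    """Pairwise Euclidean distance matrix of one centroid per group."""
    items = list(centroids.items()) if isinstance(centroids, Mapping) else list(centroids)
    labels = [str(lab) for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in centroid set")
    coords = np.asarray([np.asarray(c, dtype=float) for _, c in items])
    dist = cdist(coords, coords, "euclidean")
    return CentroidDistanceMatrix(labels=tuple(labels), distances=dist)


@dataclass
class BrainAgeReport:
    """1-D brain-age distances from the reference centroid.

    ``distances`` maps each group to its Euclidean distance from the
    reference group's centroid (reference at 0).  ``attenuation_pct`` maps
    age (months) to the integer-rounded percent by which exercise reduces
    that distance, ``100 * (d_control - d_RW) / d_control``; full-precision
    values sit in ``attenuation_exact``.
    """

    reference: ClassLabel
    distances: Dict[str, float]
    attenuation_pct: Dict[int, int]
    attenuation_exact: Dict[int, float]

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.short,
            "distances": self.distances,
            "attenuation_pct": {str(a): v for a, v in self.attenuation_pct.items()},
            "attenuation_exact": {str(a): v for a, v in self.attenuation_exact.items()},
        }


def brain_age(matrix: CentroidDistanceMatrix, reference: LabelLike) -> BrainAgeReport:
    """Distances to the reference (young-RW) centroid and exercise attenuation.

    For every age with both a control and an RW group in the matrix, the
    percent attenuation of the control distance achieved by exercise is
    reported (rounded to the nearest integer); ages missing one condition
    are omitted with a warning.
    """
    ref = ClassLabel.parse(reference)
    if ref.short not in matrix.labels:
        raise ValueError(f"reference group {ref.short} not present in the distance matrix")
    present = {ClassLabel.parse(lab) for lab in matrix.labels}
    distances = {lab: matrix.distance(ref.short, lab) for lab in matrix.labels}

    att_pct: Dict[int, int] = {}
    att_exact: Dict[int, float] = {}
    for age in sorted({lab.age_months for lab in present}):
        control, rw = ClassLabel(age, False), ClassLabel(age, True)
        if ref in (control, rw):
            continue  # the reference age has no meaningful attenuation vs itself
        if control not in present or rw not in present:
            warnings.warn(f"age {age}: control or RW group missing; attenuation omitted",
                          stacklevel=2)
            continue
        d_c = distances[control.short]
        d_rw = distances[rw.short]
        if d_c == 0:
            warnings.warn(f"age {age}: zero control distance; attenuation omitted", stacklevel=2)
            continue
        exact = 100.0 * (d_c - d_rw) / d_c
        att_exact[age] = exact
        att_pct[age] = int(round(exact))
    return BrainAgeReport(
        reference=ref,
        distances=distances,
        attenuation_pct=att_pct,
        attenuation_exact=att_exact,
    )
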