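"""Ward-seeded K-means clustering engine.

K-means minimizes the within-group sum of squared errors

    J(C) = sum_k sum_{x_i in c_k} || x_i - mu_k ||^2

but with random initialization its output varies between runs, which is
unacceptable when group membership carries regulatory weight.  This engine
therefore seeds K-means with the centers of a Ward's minimum-variance
hierarchical clustering cut at K: Ward's algorithm is deterministic, so the
full 2-step procedure returns the same partition every time it is run on
the same data, and the seeded start empirically dominates large batches of
random starts.

Refinement is plain Lloyd SSE descent with two deterministic conventions:
nearest-center ties go to the lowest group index, and a group emptied
during refinement is re-seeded with the point farthest from its current
center (so the solution keeps exactly K groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .data_model import InputError
from .features import FeatureMatrix

#: relative SSE change below which Lloyd iteration is considered converged
CONVERGENCE_TOL = 1e-10
MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """K-means refinement failed to converge; carries the SSE trace."""

    def __init__(self, trace: list[float]):
        super().__init__(
            f"k-means did not converge in {len(trace)} iterations; "
            f"last SSE values {trace[-3:]}"
        )
        self.trace = trace


@dataclass
class ClusterSolution:
    """One partition of the facilities with its fit statistics.

    ``rss`` is J(C); ``tss`` is the total sum of squares about the grand
    mean; ``r2 = 1 - rss/tss`` measures overall fit.
    """

    facilities: list[str]
    labels: np.ndarray          # (n,) int group indices 0..K-1
    centers: np.ndarray         # (K, m) group means
    rss: float
    tss: float
    r2: float
    method: str = "ward+kmeans"

    @property
    def K(self) -> int:
        return self.centers.shape[0]

    def assignments(self) -> dict[str, int]:
        """facility_id -> 1-based group index."""
        return {f: int(g) + 1 for f, g in zip(self.facilities, self.labels)}

    def group_sizes(self, member_counts: np.ndarray | None = None) -> np.ndarray:
        """Size of each group in underlying facilities.

        ``member_counts`` (per observation) lets merged tandem observations
        count all their member hospitals; default 1 per observation.
        """
        if member_counts is None:
            member_counts = np.ones(len(self.facilities), dtype=int)
        return np.bincount(self.labels, weights=member_counts, minlength=self.K).astype(int)


def _sse(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def _centers(X: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    centers = np.empty((K, X.shape[1]))
    for k in range(K):
        centers[k] = X[labels == k].mean(axis=0)
    return centers


def fit_stats(features: FeatureMatrix, labels) -> tuple[float, float, float]:
    """(rss, tss, r2) for an arbitrary partition of the facilities.

    ``labels`` may be an integer array aligned with ``features.facilities``
    or a mapping facility_id -> group label (any hashable labels).  Centers
    are the group means, so this scores external partitions — e.g. a legacy
    configuration — on the same footing as K-means output.
    """
    X = features.values
    if isinstance(labels, dict):
        unknown = set(labels) - set(features.facilities)
        if unknown:
            raise InputError(f"unknown facilities in assignment: {sorted(unknown)}")
        missing = set(features.facilities) - set(labels)
        if missing:
            raise InputError(f"facilities missing from assignment: {sorted(missing)}")
        raw = [labels[f] for f in features.facilities]
        uniq = sorted(set(raw), key=lambda v: str(v))
        lab = np.array([uniq.index(v) for v in raw])
    else:
        lab = np.asarray(labels, dtype=int)
        if lab.shape[0] != X.shape[0]:
            raise InputError("label vector length does not match facility count")
        _, lab = np.unique(lab, return_inverse=True)
    K = int(lab.max()) + 1
    centers = _centers(X, lab, K)
    rss = _sse(X, lab, centers)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return rss, tss, r2


def _solution(features: FeatureMatrix, labels: np.ndarray, method: str) -> ClusterSolution:
    X = features.values
    K = int(labels.max()) + 1
    centers = _centers(X, labels, K)
    rss = _sse(X, labels, centers)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return ClusterSolution(
        facilities=list(features.facilities),
        labels=labels.copy(),
        centers=centers,
        rss=rss,
        tss=tss,
        r2=max(0.0, r2),
        method=method,
    )


def ward_linkage(features: FeatureMatrix) -> np.ndarray:
    """Ward minimum-variance agglomeration tree over the feature rows."""
    return linkage(features.values, method="ward")


def ward_partition(
    features: FeatureMatrix, K: int, Z: np.ndarray | None = None
) -> ClusterSolution:
    """Cut the Ward tree at K groups (deterministic seeding partition)."""
    n = features.n
    if not 1 <= K <= n:
        raise InputError(f"K={K} out of range 1..{n}")
    if K == n:
        labels = np.arange(n)
    else:
        if Z is None:
            Z = ward_linkage(features)
        raw = fcluster(Z, t=K, criterion="maxclust")
        _, labels = np.unique(raw, return_inverse=True)
    return _solution(features, labels, method="ward")


def kmeans_refine(features: FeatureMatrix, seed_centers: np.ndarray) -> ClusterSolution:
    """Lloyd SSE descent from given seed centers, run to convergence.

    Guarantees ``rss <= rss(seed partition)`` because the very first
    assign-to-nearest/recompute-means step cannot increase J(C).
    """
    X = features.values
    centers = np.asarray(seed_centers, dtype=float).copy()
    if not np.isfinite(centers).all():
        raise InputError("seed centers must be finite")
    K = centers.shape[0]
    if K > X.shape[0]:
        raise InputError(f"K={K} exceeds n={X.shape[0]}")

    trace: list[float] = []
    prev_sse = np.inf
    for _ in range(MAX_ITER):
        D = cdist(X, centers, metric="sqeuclidean")
        labels = D.argmin(axis=1)  # argmin takes the lowest index on ties
        # repair emptied groups with the point farthest from its current center,
        # drawn from a group that can spare it (>= 2 members)
        empty = [k for k in range(K) if not (labels == k).any()]
        if empty:
            resid = D[np.arange(len(labels)), labels].copy()
            for k in empty:
                sizes = np.bincount(labels, minlength=K)
                eligible = sizes[labels] >= 2
                cand = np.where(eligible, resid, -np.inf)
                donor = int(cand.argmax())
                labels[donor] = k
                resid[donor] = -np.inf  # a reseeded point cannot be moved again
        centers = _centers(X, labels, K)
        sse = _sse(X, labels, centers)
        trace.append(sse)
        if prev_sse - sse <= CONVERGENCE_TOL * max(prev_sse, 1.0):
            sol = _solution(features, labels, method="kmeans")
            return sol
        prev_sse = sse
    raise ConvergenceError(trace)


def ward_kmeans(features: FeatureMatrix, K: int, Z: np.ndarray | None = None) -> ClusterSolution:
    """The full 2-step procedure: Ward cut at K, then K-means refinement."""
    seed = ward_partition(features, K, Z=Z)
    if K == 1 or K == features.n:
        return seed  # nothing to refine
    refined = kmeans_refine(features, seed.centers)
    refined.method = "ward+kmeans"
    return refined


def sweep(
    features: FeatureMatrix, k_min: int = 2, k_max: int | None = None
) -> list[ClusterSolution]:
    """One Ward-seeded, K-means-refined solution for each K.

    Returns solutions for K = 1, k_min, ..., k_max ordered by K.  The K = 1
    reference (r2 = 0 by construction) is included because the incremental-F
    statistic at K = 2 needs it.  Default range is 2..n-1.
    """
    n = features.n
    if n < 3:
        raise InputError("need at least 3 facilities to sweep K")
    if k_max is None:
        k_max = n - 1
    if not 2 <= k_min <= k_max <= n - 1:
        raise InputError(f"invalid K range {k_min}..{k_max} for n={n}")
    Z = ward_linkage(features)
    solutions = [ward_kmeans(features, 1, Z=Z)]
    for K in range(k_min, k_max + 1):
        solutions.append(ward_kmeans(features, K, Z=Z))
    return solutions


def random_start_experiment(
    features: FeatureMatrix, K: int, runs: int, seed: int
) -> tuple[list[float], float]:
    """Compare Ward seeding against repeated random-start K-means.

    Each run draws K distinct observations as initial centers (Forgy
    initialization) from a seeded generator and refines to convergence.
    Returns the list of random-start RSS values and the Ward-seeded RSS.
    """
    if runs < 1:
        raise InputError("runs must be >= 1")
    rng = np.random.default_rng(seed)
    X = features.values
    rss_values = []
    for _ in range(runs):
        pick = rng.choice(X.shape[0], size=K, replace=False)
        sol = kmeans_refine(features, X[pick])
        rss_values.append(sol.rss)
    seeded = ward_kmeans(features, K)
    return rss_values, seeded.rss
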