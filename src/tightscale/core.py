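"""The classical tight-clustering sub-algorithm.

Given a (manageable-size) expression matrix, tight clustering extracts
the single tightest *stable* cluster:

1. For a number of clusters ``k``, repeatedly subsample the rows, run
   K-means, assign every row to its nearest centroid, and average the
   resulting co-membership indicators over ``B`` resamples.  Entry
   (i, j) of the co-membership matrix is the fraction of resamples in
   which rows i and j land in the same K-means cluster.
2. Candidate tight clusters at ``k`` are maximal row sets whose pairwise
   co-membership is at least ``1 - alpha`` (found by complete-linkage
   grouping of ``1 - D`` cut at height ``alpha``), ranked by size.
3. A candidate is *stable* when nearly the same set (Jaccard similarity
   at least ``beta``) reappears among the candidates at ``k + 1``.  The
   first ``k`` (scanning k0, k0+1, ...) with a stable pair yields the
   cluster; its rows are removed and the search repeats for the next
   cluster.

The K-means local-minimum problem is handled with a hierarchical
sub-clustering initialization: centroids seeded from an average-linkage
tree cut at ``k``, with additional k-means++ restarts, keeping the run
with the best within-cluster sum of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix
from .similarity import TightnessRule, sigma

__all__ = [
    "CoreParams",
    "comembership",
    "candidate_clusters",
    "tightest_stable_cluster",
    "tight_clust",
    "CoreResult",
]

# Hierarchical initialization uses at most this many points of a resample;
# average linkage on the full resample would dominate run time without
# improving the seeding of small-k K-means.
_HIER_INIT_CAP = 300


@dataclass
class CoreParams:
    """Tuning parameters of the core tight-clustering routine.

    B : resamples averaged into the co-membership matrix
    k0 : first (smallest) number of K-means clusters tried
    m : maximum number of consecutive k values tried for stability
    subsample_frac : fraction of rows drawn (without replacement) per resample
    alpha : co-membership slack; candidates need pairwise co-membership >= 1-alpha
    beta : Jaccard threshold for stability between candidates at k and k+1
    q : number of top (largest) candidates retained per k
    n_restarts : total K-means starts per resample; the first start is
        hierarchically initialized, any further ones are k-means++ and the
        best within-cluster sum of squares wins.  The default of 1 keeps
        K-means deterministic given the resample, which is what makes
        co-membership averages concentrate; extra restarts trade that
        consistency for lower per-run distortion.
    seed : integer seed; all randomness derives from it
    """

    B: int = 10
    k0: int = 7
    m: int = 3
    subsample_frac: float = 0.7
    alpha: float = 0.1
    beta: float = 0.7
    q: int = 7
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.subsample_frac < 1):
            raise ValueError("subsample_frac must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1)")
        for name in ("B", "m", "q", "k0", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


def _derive_rng(seed: int, *tags: int) -> np.random.Generator:
    """Deterministic child generator from a base seed and integer tags."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, tags)]))


def _hier_init_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Initial centroids from an average-linkage tree cut at k."""
    n = X.shape[0]
    if n > _HIER_INIT_CAP:
        sub = rng.choice(n, _HIER_INIT_CAP, replace=False)
        Xs = X[sub]
    else:
        Xs = X
    Z = linkage(Xs, method="average")
    lab = fcluster(Z, t=k, criterion="maxclust")
    cents = np.array([Xs[lab == c].mean(axis=0) for c in np.unique(lab)])
    if cents.shape[0] < k:  # tree produced fewer groups (duplicate points)
        extra = Xs[rng.choice(Xs.shape[0], k - cents.shape[0], replace=True)]
        cents = np.vstack([cents, extra])
    return cents


def _fit_kmeans(X: np.ndarray, k: int, params: CoreParams, rng: np.random.Generator) -> np.ndarray:
    """Best-of-restarts K-means centroids for one resample."""
    seeds = rng.integers(0, 2**31 - 1, size=2)
    init = _hier_init_centroids(X, k, rng)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100, random_state=int(seeds[0])).fit(X)
    best = km
    extra = params.n_restarts - 1
    if extra > 0:
        km2 = KMeans(
            n_clusters=k, init="k-means++", n_init=extra, max_iter=100, random_state=int(seeds[1])
        ).fit(X)
        if km2.inertia_ < best.inertia_:
            best = km2
    return best.cluster_centers_


def comembership(
    matrix: ExpressionMatrix | np.ndarray,
    k: int,
    params: CoreParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Average K-means co-membership over ``params.B`` row subsamples.

    Every row (sampled or not) is assigned to its nearest centroid so the
    matrix covers all rows.  Entries are multiples of 1/B, symmetric,
    with unit diagonal.
    """
    X = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("input matrix contains non-finite values")
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"matrix has {n} rows, fewer than k={k}")
    if rng is None:
        rng = _derive_rng(params.seed, k)
    s = max(k, math.ceil(params.subsample_frac * n))
    counts = np.zeros((n, n), dtype=np.uint16)
    for _ in range(params.B):
        sub = rng.choice(n, size=s, replace=False)
        centroids = _fit_kmeans(X[sub], k, params, rng)
        labels = cdist(X, centroids).argmin(axis=1)
        counts += labels[:, None] == labels[None, :]
    return counts / float(params.B)


def candidate_clusters(D: np.ndarray, params: CoreParams) -> list[np.ndarray]:
    """Candidate tight clusters from a co-membership matrix.

    Complete-linkage grouping of ``1 - D`` cut at height ``alpha``
    guarantees pairwise co-membership >= ``1 - alpha`` inside every
    returned group.  Up to ``q`` groups are returned, largest first,
    ties broken by smallest first row index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 1:
        return [np.array([0])]
    dist = 1.0 - D
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    lab = fcluster(Z, t=params.alpha, criterion="distance")
    groups = [np.flatnonzero(lab == c) for c in np.unique(lab)]
    groups.sort(key=lambda g: (-g.size, int(g[0])))
    return groups[: params.q]


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b, assume_unique=True).size
    if inter == 0:
        return 0.0
    return inter / float(a.size + b.size - inter)


def tightest_stable_cluster(
    matrix: ExpressionMatrix | np.ndarray, params: CoreParams
) -> np.ndarray | None:
    """Extract the tightest stable cluster, or ``None`` if none is found.

    Scans k = k0, k0+1, ..., k0+m-1; at the first k where some size->=2
    candidate at k and one at k+1 have Jaccard similarity >= beta, the
    k+1 member of the highest-similarity stable pair is returned (ties
    by candidate rank).  Similarity priority makes the *most
    reproducible* candidate win, which is what lets a markedly tighter
    cluster beat a larger but noise-frayed one.  Row indices are local
    to ``matrix``.
    """
    X = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    cache: dict[int, list[np.ndarray]] = {}

    def cands(k: int) -> list[np.ndarray]:
        if k not in cache:
            D = comembership(X, k, params, rng=_derive_rng(params.seed, k))
            cache[k] = [g for g in candidate_clusters(D, params) if g.size >= 2]
        return cache[k]

    for step in range(params.m):
        k = params.k0 + step
        if k + 1 > n - 1:
            break  # not enough rows left to ask for k+1 clusters
        A, B2 = cands(k), cands(k + 1)
        best, best_sim = None, -1.0
        for V in A:  # candidates ranked largest-first; rank breaks ties
            for Vp in B2:
                s = _jaccard(V, Vp)
                if s >= params.beta and s > best_sim:
                    best, best_sim = Vp, s
        if best is not None:
            return np.sort(best)
    return None


@dataclass
class CoreResult:
    """Sequentially extracted tight clusters plus the residual noise set."""

    clusters: list = field(default_factory=list)
    noise: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    sigmas: list = field(default_factory=list)


def tight_clust(
    matrix: ExpressionMatrix,
    n_target: int,
    params: CoreParams | None = None,
    tightness: TightnessRule | str = "mst_avg_edge",
    k0: int | None = None,
) -> CoreResult:
    """Extract up to ``n_target`` tight clusters, one at a time.

    The first extraction starts the stability scan at ``k0`` (default
    ``n_target + 5``); the start decrements (floor 2) as clusters are
    removed.  With K-means granularity well above the natural cluster
    count the routine deliberately returns tight *cores*, so callers
    after whole coarse clusters should pass a ``k0`` near the expected
    cluster number.  Remaining rows are reported as noise.
    """
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    params = params or CoreParams()
    k_start = n_target + 5 if k0 is None else int(k0)
    remaining = np.arange(matrix.n)
    result = CoreResult()
    for t in range(n_target):
        if remaining.size < 3:
            break
        p_t = replace(params, k0=max(2, k_start - t), seed=(params.seed * 1009 + t) & 0x7FFFFFFF)
        sub = matrix.subset(remaining)
        local = tightest_stable_cluster(sub, p_t)
        if local is None:
            break
        cluster = remaining[local]
        result.clusters.append(cluster)
        result.sigmas.append(sigma(cluster, matrix, tightness))
        remaining = np.setdiff1d(remaining, cluster, assume_unique=True)
    result.noise = remaining
    return result
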