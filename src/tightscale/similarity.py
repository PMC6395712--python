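"""Cluster-pair decision functions and cluster tightness measures.

Two families of primitives live here:

* **Decision functions** ``pi(C, C') -> {0, 1}`` decide whether two
  clusters have similar enough profiles to be merged into one.  Every
  rule satisfies ``pi(empty, C) = pi(C, empty) = 0`` and is symmetric.
  The default rule compares minimum-spanning-tree (MST) maximum edge
  lengths: two tight clusters belong together exactly when joining them
  does not require a long bridge edge, i.e. when
  ``2 * d_mst(C u C') <= d_mst(C) + d_mst(C')``.

* **Tightness measures** ``sigma(C) -> R+`` score how dispersed a
  cluster is (smaller = tighter).  All five offered measures are
  translation- and rotation-invariant.  The default is the mean edge
  length of the Euclidean MST, the natural companion of the MST
  decision rule.

Clusters are represented as integer row-index arrays into an
:class:`~tightscale.matrix.ExpressionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DecisionRule",
    "TightnessRule",
    "mst_edge_lengths",
    "mst_max_edge",
    "pi_mst",
    "pi_distance_ratio",
    "pi_ward",
    "sigma",
    "SIGMA_KINDS",
    "PI_KINDS",
]

#: relative tie tolerance so identical clusters merge under floating point
EPS_TIE = 1e-12

PI_KINDS = ("mst", "distance_ratio", "ward")
SIGMA_KINDS = (
    "trace_var",
    "max_eigen",
    "prod_nonzero_eigen",
    "max_pairwise",
    "mst_avg_edge",
)

# Above this many points Prim recomputes distance rows on the fly instead
# of materializing the full pairwise matrix.
_DENSE_LIMIT = 4000


def mst_edge_lengths(points: np.ndarray) -> np.ndarray:
    """Edge lengths of a Euclidean minimum spanning tree (Prim's algorithm).

    Parameters
    ----------
    points : ndarray (m, d)
        At least one point.

    Returns
    -------
    ndarray of m-1 edge lengths (empty for a single point).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    m = points.shape[0]
    if m == 0:
        raise ValueError("MST of an empty point set is undefined")
    if m == 1:
        return np.empty(0)
    if m <= _DENSE_LIMIT:
        D = cdist(points, points)
        row = lambda j: D[j]  # noqa: E731
    else:
        row = lambda j: np.sqrt(((points - points[j]) ** 2).sum(axis=1))  # noqa: E731
    best = row(0)
    best[0] = np.inf
    in_tree = np.zeros(m, dtype=bool)
    in_tree[0] = True
    edges = np.empty(m - 1)
    for t in range(m - 1):
        j = int(np.argmin(best))
        edges[t] = best[j]
        in_tree[j] = True
        np.minimum(best, row(j), out=best)
        best[in_tree] = np.inf
    return edges


def mst_max_edge(points: np.ndarray) -> float:
    """Maximum edge length of the Euclidean MST; 0 for a single point."""
    edges = mst_edge_lengths(points)
    return float(edges.max()) if edges.size else 0.0


def _points(cluster, matrix) -> np.ndarray:
    idx = np.asarray(list(cluster), dtype=int)
    return matrix.rows(idx)


def pi_mst(C, Chat, matrix, printed: bool = False) -> int:
    """MST decision: merge when joining the clusters needs no long bridge.

    Returns 1 iff ``2 * d_mst(C u C') <= d_mst(C) + d_mst(C')`` (up to a
    relative tie tolerance), where ``d_mst`` is the MST maximum edge
    length; 0 if either cluster is empty.  With ``printed=True`` the
    opposite inequality (strict ``>``) is used instead.
    """
    C = np.asarray(list(C), dtype=int)
    Chat = np.asarray(list(Chat), dtype=int)
    if C.size == 0 or Chat.size == 0:
        return 0
    a = mst_max_edge(matrix.rows(C))
    b = mst_max_edge(matrix.rows(Chat))
    u = mst_max_edge(matrix.rows(np.union1d(C, Chat)))
    if printed:
        return int(2.0 * u > a + b)
    return int(2.0 * u <= a + b + EPS_TIE * max(1.0, a + b))


def pi_distance_ratio(C, Chat, matrix, gamma: float = 0.5) -> int:
    """Merge when average cross-distance / maximum cross-distance < gamma.

    The ratio is infinite when either cluster is empty (never merge).
    Two coincident single points give 0/0, defined here as 0 (merge).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    C = np.asarray(list(C), dtype=int)
    Chat = np.asarray(list(Chat), dtype=int)
    if C.size == 0 or Chat.size == 0:
        return 0
    cross = cdist(matrix.rows(C), matrix.rows(Chat))
    mx = cross.max()
    d = 0.0 if mx == 0 else float(cross.mean() / mx)
    return int(d < gamma)


def pi_ward(C, Chat, matrix, gamma: float) -> int:
    """Ward-style decision: merge when the within-variance increase
    |C||C'|/(|C|+|C'|) * ||mean(C) - mean(C')||^2 stays below gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    C = np.asarray(list(C), dtype=int)
    Chat = np.asarray(list(Chat), dtype=int)
    if C.size == 0 or Chat.size == 0:
        return 0
    mc = matrix.rows(C).mean(axis=0)
    mh = matrix.rows(Chat).mean(axis=0)
    nc, nh = len(C), len(Chat)
    increase = nc * nh / (nc + nh) * float(((mc - mh) ** 2).sum())
    return int(increase < gamma)


@dataclass
class DecisionRule:
    """A configured merge decision ``pi``.

    kind : 'mst' (default), 'distance_ratio' or 'ward'
    gamma : threshold used by the distance_ratio and ward rules
    printed_mst : use the literal (non-rationale) MST inequality direction
    """

    kind: str = "mst"
    gamma: float = 0.5
    printed_mst: bool = False

    def __post_init__(self):
        if self.kind not in PI_KINDS:
            raise ValueError(f"unknown decision rule {self.kind!r}")

    def decide(self, C, Chat, matrix) -> int:
        if self.kind == "mst":
            return pi_mst(C, Chat, matrix, printed=self.printed_mst)
        if self.kind == "distance_ratio":
            return pi_distance_ratio(C, Chat, matrix, self.gamma)
        return pi_ward(C, Chat, matrix, self.gamma)


@dataclass
class TightnessRule:
    """A configured tightness measure ``sigma`` (smaller = tighter)."""

    kind: str = "mst_avg_edge"

    def __post_init__(self):
        if self.kind not in SIGMA_KINDS:
            raise ValueError(f"unknown tightness rule {self.kind!r}")


def sigma(C, matrix, rule: TightnessRule | str = "mst_avg_edge") -> float:
    """Dispersion of a cluster under the chosen rule.

    Rules (all shift/rotation invariant):

    - ``trace_var``: trace of the coordinate covariance (divisor n-1)
    - ``max_eigen``: largest covariance eigenvalue
    - ``prod_nonzero_eigen``: product of non-negligible covariance eigenvalues
    - ``max_pairwise``: cluster diameter
    - ``mst_avg_edge``: mean Euclidean-MST edge length (default)

    Raises for clusters with fewer than two points: singletons have no
    defined tightness and must never be ranked.
    """
    kind = rule.kind if isinstance(rule, TightnessRule) else rule
    if kind not in SIGMA_KINDS:
        raise ValueError(f"unknown tightness rule {kind!r}")
    P = _points(C, matrix)
    if P.shape[0] < 2:
        raise ValueError("tightness is undefined for clusters of size < 2")
    if kind == "mst_avg_edge":
        return float(mst_edge_lengths(P).mean())
    if kind == "max_pairwise":
        return float(cdist(P, P).max())
    cov = np.cov(P, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if kind == "trace_var":
        return float(np.trace(cov))
    eig = np.linalg.eigvalsh(cov)
    if kind == "max_eigen":
        return float(eig[-1])
    # prod_nonzero_eigen: drop numerically-zero directions
    tol = eig[-1] * 1e-10
    nz = eig[eig > tol]
    return float(np.prod(nz)) if nz.size else 0.0
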