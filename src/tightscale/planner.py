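"""Partition/repetition planning and the concordance-probability model.

With chunks of at most ``M`` rows, a matrix of ``n`` rows is split into
``L = ceil(n / M)`` parts, and the split is repeated ``R`` times to
undo the damage partitioning does to clusters that straddle chunk
boundaries.  The probability that two rows of the true tightest cluster
end up clustered together ("concordance") is

    1 - 2^{-R} * [ (1 - p1)^{R(R-1)} + (1 - p2)^{R} ]

where ``p1`` (``p2``) is the probability that two chunk-level cluster
fragments, overlapping (respectively disjoint), are merged by the
decision function.  The bound over *all* row pairs motivates the
conservative repetition count

    R'(n) = ceil[ (log(1-p) - 2 log n) / (-log 2 + log(1 - L/n)) ]

(natural logarithms; the unknown p2 replaced by the conservative
polynomial assumption p2 = L/n).  In practice noise rows accumulate in
the bucket as R grows, so the default plan uses the small practical
value R = 3; the theoretical R'(n) is available on request, and a
compute budget ``Lambda`` caps R x L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScalePlan",
    "ConcordanceParams",
    "concordance_probability",
    "concordance_lower_bound",
    "r_prime",
    "plan",
    "PRACTICAL_R",
    "DEFAULT_P",
]

#: default all-pairs concordance target
DEFAULT_P = 0.95
#: repetition count used by default (noise accumulates for large R)
PRACTICAL_R = 3


@dataclass
class ConcordanceParams:
    """Merge probabilities of the concordance model (both in [0, 1])."""

    p1: float
    p2: float

    def __post_init__(self):
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ScalePlan:
    """Partition/repetition parameters of one scaled run."""

    M: int
    L: int
    R: int
    Lambda: float = math.inf
    p: float = DEFAULT_P

    def __post_init__(self):
        if self.M < 1 or self.L < 1 or self.R < 1:
            raise ValueError("M, L and R must be positive")
        if self.R * self.L > self.Lambda:
            raise ValueError("R x L exceeds the budget Lambda")


def concordance_probability(R: int, cp: ConcordanceParams) -> float:
    """Probability two tightest-cluster rows are clustered together.

    ``1 - 2^{-R} [ (1-p1)^{R(R-1)} + (1-p2)^{R} ]``; the partition
    factor ``{C(L,2)/(L(L-1))}^R`` equals ``2^{-R}`` for every L.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    return 1.0 - 2.0**-R * ((1.0 - cp.p1) ** (R * (R - 1)) + (1.0 - cp.p2) ** R)


def concordance_lower_bound(n: int, R: int, p2: float) -> float:
    """All-pairs concordance bound ``1 - 2^{-R} n^2 (1-p2)^R``.

    May be negative for small R; it is a Boole-inequality union bound
    over all n^2/2 row pairs, doubled.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    return 1.0 - 2.0**-R * n * n * (1.0 - p2) ** R


def r_prime(n: int, L: int, p: float = DEFAULT_P) -> int:
    """Smallest conservative repetition count achieving target ``p``.

    ``ceil[(log(1-p) - 2 log n) / (-log 2 + log(1 - 1/(n/L)))]`` with
    natural logarithms; requires chunks of more than one row (n/L > 1).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    if n / L <= 1:
        raise ValueError("n/L must exceed 1")
    num = math.log(1.0 - p) - 2.0 * math.log(n)
    den = -math.log(2.0) + math.log(1.0 - 1.0 / (n / L))
    return max(1, math.ceil(num / den))


def plan(
    n: int,
    M: int,
    p: float = DEFAULT_P,
    Lambda: float = math.inf,
    practical: bool = True,
    repeats: int | None = None,
) -> ScalePlan:
    """Build a :class:`ScalePlan` for an n-row matrix with chunk size M.

    ``L = ceil(n/M)``; ``R = min(R'(n), floor(Lambda/L))`` (floored at
    1).  By default the practical choice R = 3 overrides the
    theoretical R'(n); pass ``practical=False`` for the theoretical
    plan, or ``repeats`` to force an explicit R (still budget-capped).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if M < 2:
        raise ValueError("M must be at least 2")
    L = math.ceil(n / M)
    if Lambda < L:
        raise ValueError(f"budget Lambda={Lambda} cannot cover even one pass (L={L})")
    cap = math.floor(Lambda / L) if math.isfinite(Lambda) else None
    if repeats is not None:
        R = int(repeats)
    elif practical:
        R = PRACTICAL_R
    elif n / L > 1:
        R = r_prime(n, L, p)
    else:
        R = 1
    if cap is not None:
        R = min(R, cap)
    R = max(1, R)
    return ScalePlan(M=M, L=L, R=R, Lambda=Lambda, p=p)
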