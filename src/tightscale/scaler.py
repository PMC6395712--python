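"""Divide-and-combine tight clustering for large matrices.

The core tight-clustering routine is only tractable on a few thousand
rows.  To scale it, each extraction iteration

1. randomly partitions the active rows into ``L`` near-equal chunks,
   independently ``R`` times (``M0 = R x L`` manageable sub-problems),
2. runs the core routine on every chunk and stores each chunk's tightest
   stable cluster in a shared *bucket* (entries carried over from
   earlier iterations stay in front),
3. applies the sequential combining operator: scanning the bucket left
   to right, each entry absorbs every later entry the decision function
   ``pi`` declares similar (absorbed entries become empty),
4. selects the bucket entry with the smallest tightness ``sigma`` as the
   next output cluster, and
5. removes its rows from the data and from every bucket entry before the
   next iteration.

Iterations stop after ``k_target`` clusters or when no selectable entry
remains; rows never extracted are reported as noise, so the sum of
cluster sizes never exceeds n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np

from .core import CoreParams, _derive_rng, tightest_stable_cluster
from .matrix import ExpressionMatrix
from .planner import ScalePlan
from .similarity import DecisionRule, TightnessRule, mst_max_edge, sigma

__all__ = [
    "Bucket",
    "ClusteringResult",
    "partition",
    "fill_bucket",
    "combine",
    "select_tightest",
    "advance",
    "run",
]


@dataclass
class Bucket:
    """Ordered pool of candidate clusters; entries may be empty arrays."""

    entries: list = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def nonempty(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if len(e) > 0]


@dataclass
class ClusteringResult:
    """Clusters in extraction (tightness) order, plus the noise rows."""

    clusters: list = field(default_factory=list)
    noise: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    sigmas: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def labels(self, n: int) -> np.ndarray:
        """Per-row labels: 1..k in extraction order, 0 for noise."""
        lab = np.zeros(n, dtype=int)
        for c, idx in enumerate(self.clusters, start=1):
            lab[np.asarray(idx, dtype=int)] = c
        return lab


def partition(
    active_rows: np.ndarray,
    L: int,
    R: int,
    seed_or_rng,
) -> list[list[np.ndarray]]:
    """R independent uniformly-random splits of the rows into L parts.

    Part sizes within one split differ by at most one; parts are
    disjoint and cover the active rows.
    """
    active = np.sort(np.asarray(list(active_rows), dtype=int))
    if L < 1 or R < 1:
        raise ValueError("L and R must be positive")
    if L > active.size:
        raise ValueError(f"cannot split {active.size} rows into L={L} parts")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    reps = []
    for _ in range(R):
        perm = rng.permutation(active)
        reps.append([np.sort(p) for p in np.array_split(perm, L)])
    return reps


def fill_bucket(
    matrix: ExpressionMatrix,
    partitions: list[list[np.ndarray]],
    core: CoreParams,
    bucket: Bucket | None = None,
) -> Bucket:
    """Run the core routine on every chunk and append the results.

    Existing bucket entries (carried over from earlier iterations) are
    preserved ahead of the new chunk-level clusters.  Chunks yielding no
    stable cluster contribute nothing.
    """
    entries = list(bucket.entries) if bucket is not None else []
    for r, parts in enumerate(partitions):
        for l, part in enumerate(parts):
            if part.size < 4:
                continue
            k0_eff = min(core.k0, part.size - core.m - 2)
            if k0_eff < 2:
                k0_eff = 2
            p = replace(
                core,
                k0=k0_eff,
                seed=int(_derive_rng(core.seed, 7, r, l).integers(0, 2**31 - 1)),
            )
            local = tightest_stable_cluster(matrix.subset(part), p)
            if local is not None:
                entries.append(part[local])
    return Bucket(entries)


def combine(
    bucket: Bucket,
    rule: DecisionRule,
    matrix: ExpressionMatrix,
    log: list | None = None,
) -> Bucket:
    """Sequential absorption: entry i absorbs every later similar entry.

    Scanning i = 0, 1, ... in order, each nonempty entry ``C_i`` is
    tested against every later nonempty ``C_j``; when ``pi = 1`` the
    rows of ``C_j`` move into ``C_i`` (which keeps growing mid-scan and
    is re-used, grown, for subsequent tests) and ``C_j`` becomes empty.
    """
    entries = [np.asarray(e, dtype=int).copy() for e in bucket.entries]
    empty = np.empty(0, dtype=int)
    # d_mst cache for the (common) MST rule; keyed by entry identity.
    dmst: dict[int, float] = {}

    def d_of(i: int) -> float:
        if i not in dmst:
            dmst[i] = mst_max_edge(matrix.rows(entries[i]))
        return dmst[i]

    for i in range(len(entries) - 1):
        if entries[i].size == 0:
            continue
        for j in range(i + 1, len(entries)):
            if entries[j].size == 0:
                continue
            if rule.kind == "mst" and not rule.printed_mst:
                a, b = d_of(i), d_of(j)
                u = mst_max_edge(matrix.rows(np.union1d(entries[i], entries[j])))
                merged = int(2.0 * u <= a + b + 1e-12 * max(1.0, a + b))
            else:
                merged = rule.decide(entries[i], entries[j], matrix)
            if merged:
                entries[i] = np.union1d(entries[i], entries[j])
                entries[j] = empty
                dmst.pop(i, None)
                dmst.pop(j, None)
                if log is not None:
                    log.append({"i": i, "j": j, "size": int(entries[i].size)})
    return Bucket(entries)


def select_tightest(
    bucket: Bucket, rule: TightnessRule, matrix: ExpressionMatrix
) -> tuple[int, np.ndarray, float] | None:
    """Nonempty bucket entry minimizing sigma (ties: earliest position).

    Entries with fewer than two members are skipped (their tightness is
    undefined).  Returns ``(position, cluster, sigma)`` or ``None`` when
    nothing is selectable, which terminates extraction.
    """
    best = None
    for i in bucket.nonempty():
        entry = np.asarray(bucket.entries[i], dtype=int)
        if entry.size < 2:
            continue
        s = sigma(entry, matrix, rule)
        if best is None or s < best[2]:
            best = (i, entry, s)
    return best


def advance(
    matrix: ExpressionMatrix,
    active_rows: np.ndarray,
    bucket: Bucket,
    selected: np.ndarray,
) -> tuple[np.ndarray, Bucket]:
    """Remove the selected cluster from the data and from every entry."""
    selected = np.asarray(selected, dtype=int)
    active = np.setdiff1d(np.asarray(active_rows, dtype=int), selected, assume_unique=False)
    entries = [np.setdiff1d(np.asarray(e, dtype=int), selected) for e in bucket.entries]
    return active, Bucket(entries)


def run(
    matrix: ExpressionMatrix,
    k_target: int,
    plan: ScalePlan,
    core: CoreParams | None = None,
    dec: DecisionRule | None = None,
    tight: TightnessRule | None = None,
    seed: int | None = None,
) -> ClusteringResult:
    """Full divide-and-combine extraction of up to ``k_target`` clusters.

    Iteration t reseeds with ``seed + t`` so partitions differ across
    iterations while the whole run stays reproducible.  The chunk count
    is lowered automatically as the active set shrinks (L_t =
    ceil(|active| / M)), and chunk-level extraction starts at
    ``k0 = k_target - t + 5``.
    """
    if k_target < 1:
        raise ValueError("k_target must be at least 1")
    core = core or CoreParams()
    dec = dec or DecisionRule()
    tight = tight or TightnessRule()
    base_seed = core.seed if seed is None else int(seed)

    active = np.arange(matrix.n)
    bucket = Bucket([])
    result = ClusteringResult()
    for t in range(k_target):
        if active.size < 4:
            break
        L_t = min(plan.L, max(1, ceil(active.size / plan.M)))
        parts = partition(active, L_t, plan.R, np.random.default_rng(base_seed + t))
        core_t = replace(core, k0=max(2, k_target - t + 5), seed=(base_seed + t) & 0x7FFFFFFF)
        bucket = fill_bucket(matrix, parts, core_t, bucket)
        filled_sizes = [int(e.size) for e in bucket.entries]
        merges: list = []
        bucket = combine(bucket, dec, matrix, log=merges)
        sel = select_tightest(bucket, tight, matrix)
        if sel is None:
            break
        pos, cluster, s = sel
        result.clusters.append(cluster)
        result.sigmas.append(s)
        active, bucket = advance(matrix, active, bucket, cluster)
        result.log.append(
            {
                "iteration": t,
                "L": L_t,
                "R": plan.R,
                "bucket_sizes_after_fill": filled_sizes,
                "merges": merges,
                "selected_position": pos,
                "selected_size": int(cluster.size),
                "selected_sigma": float(s),
                "active_remaining": int(active.size),
            }
        )
    result.noise = active
    return result
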