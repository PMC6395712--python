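"""Synthetic gene-expression data and clustering evaluation.

The generator emulates the standard template-plus-noise microarray
simulation scheme: each of ``n_c`` clusters is a Gaussian template
profile (i.i.d. coordinates ~ N(0, template_sd^2)) and each clustered
gene is its template plus i.i.d. N(0, within_sd^2) noise.  A stated
fraction of *scattered* genes is drawn i.i.d. N(0, template_sd^2 +
within_sd^2) per coordinate — the same marginal variance as clustered
genes, so noise is not trivially separable — and all rows are shuffled.

Evaluation uses the Rand index and a *modified* Rand index: a convex
combination of (a) the Rand index over all genes with the noise genes
treated as one extra class, and (b) the Rand index restricted to
truly-clustered genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
from scipy.special import comb

from .core import CoreParams
from .matrix import ExpressionMatrix
from .planner import plan
from .scaler import ClusteringResult, run
from .similarity import DecisionRule, TightnessRule

__all__ = [
    "SimConfig",
    "LabeledData",
    "simulate",
    "rand_index",
    "modified_rand",
    "simulation_protocol",
    "replicate_simulation_cell",
]


@dataclass
class SimConfig:
    """Simulation scenario: size, dimensionality, cluster and noise structure."""

    n: int = 10000
    d: int = 10
    n_c: int = 5
    noise_frac: float = 0.05
    min_cluster: int = 20
    template_sd: float = 2.0
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.d < 1 or self.n_c < 1:
            raise ValueError("n, d and n_c must be positive")
        if not (0.0 <= self.noise_frac < 1.0):
            raise ValueError("noise_frac must lie in [0, 1)")
        if self.template_sd <= 0 or self.within_sd <= 0:
            raise ValueError("template_sd and within_sd must be positive")
        n_noise = floor(self.noise_frac * self.n)
        if self.n - n_noise < self.n_c * self.min_cluster:
            raise ValueError(
                f"cannot fit {self.n_c} clusters of >= {self.min_cluster} genes "
                f"into {self.n - n_noise} non-noise genes"
            )


@dataclass
class LabeledData:
    """A simulated matrix plus its generating labels (0 = noise)."""

    matrix: ExpressionMatrix
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def simulate(config: SimConfig) -> LabeledData:
    """Draw one dataset; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_noise = floor(config.noise_frac * config.n)
    n_clustered = config.n - n_noise
    extra = rng.multinomial(
        n_clustered - config.n_c * config.min_cluster,
        np.full(config.n_c, 1.0 / config.n_c),
    )
    sizes = config.min_cluster + extra
    templates = rng.normal(0.0, config.template_sd, size=(config.n_c, config.d))
    blocks, labels = [], []
    for c in range(config.n_c):
        blocks.append(templates[c] + rng.normal(0.0, config.within_sd, size=(sizes[c], config.d)))
        labels.append(np.full(sizes[c], c + 1, dtype=int))
    noise_sd = float(np.hypot(config.template_sd, config.within_sd))
    blocks.append(rng.normal(0.0, noise_sd, size=(n_noise, config.d)))
    labels.append(np.zeros(n_noise, dtype=int))
    values = np.vstack(blocks)
    lab = np.concatenate(labels)
    perm = rng.permutation(config.n)
    values, lab = values[perm], lab[perm]
    ids = [f"g{i:06d}" for i in range(config.n)]
    cols = [f"s{j}" for j in range(config.d)]
    return LabeledData(ExpressionMatrix(values, ids, cols), lab)


def rand_index(a, b) -> float:
    """Fraction of unordered pairs on which two labelings agree.

    A pair agrees when both labelings put it together, or both apart.
    Computed from the contingency table in O(#distinct labels^2).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    C = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(C, (ai, bi), 1)
    total = comb(n, 2, exact=True)
    sum_ij = int(comb(C, 2).sum())
    sum_a = int(comb(C.sum(axis=1), 2).sum())
    sum_b = int(comb(C.sum(axis=0), 2).sum())
    return (total + 2 * sum_ij - sum_a - sum_b) / total


def _noise_to_singletons(lab: np.ndarray) -> np.ndarray:
    out = lab.copy()
    noise = np.flatnonzero(out == 0)
    out[noise] = -1 - np.arange(noise.size)  # unique negative classes
    return out


def modified_rand(
    truth,
    predicted,
    weight: float = 0.5,
    noise_as_singletons: bool = False,
) -> float:
    """Convex combination of the with-noise and without-noise Rand indices.

    ``weight * Rand(all genes, noise as one class) + (1 - weight) *
    Rand(restricted to truly-clustered genes)``.  With
    ``noise_as_singletons=True`` every noise gene (in either labeling)
    forms its own class in the with-noise component instead.
    """
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    mask = truth != 0
    if mask.sum() < 2:
        raise ValueError("fewer than two non-noise genes; modified Rand undefined")
    if noise_as_singletons:
        with_noise = rand_index(_noise_to_singletons(truth), _noise_to_singletons(predicted))
    else:
        with_noise = rand_index(truth, predicted)
    without = rand_index(truth[mask], predicted[mask])
    return weight * with_noise + (1.0 - weight) * without


def simulation_protocol(
    n: int = 10000,
    d: int = 10,
    n_c: int = 5,
    noise_frac: float = 0.05,
    seed: int = 0,
    M: int = 2000,
    R: int = 3,
    k_extra: int = 2,
    weight: float = 0.5,
    sim_kwargs: dict | None = None,
    core: CoreParams | None = None,
) -> tuple[float, ClusteringResult, LabeledData]:
    """One simulate -> cluster -> score pass at a simulation-grid setting.

    Simulates a dataset, runs the scaled algorithm with chunk size ``M``,
    ``R`` repetitions, the MST decision rule and mean-MST-edge tightness,
    asking for ``n_c + k_extra`` clusters, and returns the modified Rand
    index (plus the raw result and data).
    """
    cfg = SimConfig(n=n, d=d, n_c=n_c, noise_frac=noise_frac, seed=seed, **(sim_kwargs or {}))
    data = simulate(cfg)
    p = plan(n=data.matrix.n, M=M, repeats=R)
    core = core or CoreParams()
    res = run(
        data.matrix,
        k_target=n_c + k_extra,
        plan=p,
        core=core,
        dec=DecisionRule(kind="mst"),
        tight=TightnessRule(kind="mst_avg_edge"),
        seed=seed,
    )
    mr = modified_rand(data.labels, res.labels(data.matrix.n), weight=weight)
    return mr, res, data


def replicate_simulation_cell(
    n: int,
    d: int,
    n_c: int,
    noise_frac: float,
    n_reps: int,
    base_seed: int = 0,
    **kwargs,
) -> tuple[float, float, list[float]]:
    """Mean and SD of the modified Rand index over seeded replicates."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    vals = []
    for i in range(n_reps):
        mr, _, _ = simulation_protocol(n=n, d=d, n_c=n_c, noise_frac=noise_frac, seed=base_seed + i, **kwargs)
        vals.append(mr)
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if n_reps > 1 else 0.0
    return float(arr.mean()), sd, vals
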