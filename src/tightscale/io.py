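"""Plain-text input/output: expression matrices, results, run configs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .scaler import ClusteringResult

__all__ = ["read_matrix", "write_matrix", "write_result", "read_labels", "RunConfig"]


def _sep_for(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def read_matrix(path, fmt: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read a delimited matrix: first column gene ids, header of sample names.

    Raises with the offending cell named for non-numeric values, with the
    duplicate list for repeated gene ids, and with the line number for
    ragged rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = _sep_for(path, fmt)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as e:  # ragged rows carry the line number
        raise ValueError(f"{path}: malformed table: {e}") from e
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate gene ids: {dups}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} "
                f"at row {bad[0]!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    m = ExpressionMatrix(values, list(df.index), list(df.columns))
    if transpose:
        m = ExpressionMatrix(m.values.T, list(df.columns), list(df.index))
    return m


def write_matrix(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    sep = _sep_for(path, fmt)
    df = pd.DataFrame(matrix.values, index=matrix.row_ids, columns=matrix.col_ids)
    df.to_csv(path, sep=sep, index_label="gene_id")


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a two-column (gene_id, label) TSV/CSV; returns ids and int labels."""
    sep = _sep_for(path, None)
    df = pd.read_csv(path, sep=sep, header=0)
    ids = [str(x) for x in df.iloc[:, 0]]
    labels = df.iloc[:, 1].astype(int).to_numpy()
    return ids, labels


@dataclass
class RunConfig:
    """Everything needed to reproduce a clustering run from disk."""

    input: str = ""
    output_prefix: str = "tightscale"
    k_target: int = 1
    chunk_size: int = 2000
    repeats: int | None = None
    theoretical_R: bool = False
    concordance_p: float = 0.95
    budget: float | None = None
    decision: str = "mst"
    gamma: float = 0.5
    pi_mst_printed: bool = False
    tightness: str = "mst_avg_edge"
    standardize: bool = False
    transpose: bool = False
    seed: int = 0
    core: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def write_result(
    result: ClusteringResult,
    matrix: ExpressionMatrix,
    prefix,
    config: RunConfig | dict | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.clusters.tsv`` and ``<prefix>.run.json``.

    Every gene appears exactly once in the TSV with its cluster number
    (1..k in extraction order, 0 = noise) and, for clustered genes, the
    tightness of its cluster.
    """
    prefix = Path(prefix)
    labels = result.labels(matrix.n)
    sig = np.full(matrix.n, np.nan)
    for c, idx in enumerate(result.clusters, start=1):
        sig[np.asarray(idx, dtype=int)] = result.sigmas[c - 1]
    tsv_path = prefix.with_suffix(prefix.suffix + ".clusters.tsv")
    df = pd.DataFrame({"gene_id": matrix.row_ids, "cluster": labels, "sigma": sig})
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")

    json_path = prefix.with_suffix(prefix.suffix + ".run.json")
    payload = {
        "config": (config.to_dict() if isinstance(config, RunConfig) else (config or {})),
        "cluster_sizes": [int(len(c)) for c in result.clusters],
        "sigmas": [float(s) for s in result.sigmas],
        "n_noise": int(len(result.noise)),
        "iterations": result.log,
    }
    json_path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return tsv_path, json_path
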