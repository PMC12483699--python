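"""Reading and writing correlation matrices, data tables, loadings and hierarchies."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import CorrelationMatrix, to_newick
from .model import UFAParams, loading_matrix

__all__ = [
    "read_correlation",
    "read_data",
    "read_input",
    "write_correlation",
    "write_loadings",
    "write_hierarchy_json",
    "read_hierarchy_json",
    "write_newick",
    "node_names",
]


def read_correlation(path: str | Path, tol: float = 1e-8) -> CorrelationMatrix:
    """Read a labelled square correlation matrix from CSV (header row + index column)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {values.shape}")
    if not np.allclose(values, values.T, atol=tol):
        raise ValueError(f"{path}: matrix is asymmetric beyond {tol}")
    values = 0.5 * (values + values.T)
    return CorrelationMatrix(values, tuple(str(c) for c in df.columns))


def read_data(path: str | Path) -> CorrelationMatrix:
    """Read an n x J data table (CSV with header), standardize columns and
    return the sample correlation matrix.  Constant columns are rejected."""
    df = pd.read_csv(path)
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric columns {bad}")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        rows, cols = np.nonzero(~np.isfinite(values))
        raise ValueError(
            f"{path}: non-finite value at row {rows[0] + 2}, column {df.columns[cols[0]]!r}"
        )
    stds = values.std(axis=0)
    constant = [df.columns[i] for i in np.nonzero(stds == 0)[0]]
    if constant:
        raise ValueError(f"{path}: constant columns cannot be standardized: {constant}")
    r = np.corrcoef(values, rowvar=False)
    return CorrelationMatrix(r, tuple(str(c) for c in df.columns))


def read_input(path: str | Path, kind: str = "correlation") -> CorrelationMatrix:
    """Dispatch on input kind: a precomputed correlation matrix or raw data."""
    if kind == "correlation":
        return read_correlation(path)
    if kind == "data":
        return read_data(path)
    raise ValueError(f"unknown input kind {kind!r}")


def write_correlation(r: CorrelationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(r.values, index=list(r.labels), columns=list(r.labels))
    df.to_csv(path, float_format="%.17g")  # round-trips float64 exactly


def node_names(q: int) -> list[str]:
    """Column names for the 2Q-1 nodes: groups G1..GQ, merges M1..M(Q-1)."""
    return [f"G{i}" for i in range(1, q + 1)] + [f"M{i}" for i in range(1, q)]


def write_loadings(params: UFAParams, path: str | Path,
                   labels: tuple[str, ...] | None = None) -> None:
    """Export the loading matrix as CSV (rows = variables, columns = nodes)."""
    q = params.hierarchy.n_groups
    if labels is None:
        labels = tuple(f"V{j + 1}" for j in range(params.hierarchy.n_vars))
    df = pd.DataFrame(loading_matrix(params), index=list(labels),
                      columns=node_names(q))
    df.to_csv(path)


def write_hierarchy_json(params: UFAParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1) + "\n")


def read_hierarchy_json(path: str | Path) -> UFAParams:
    return UFAParams.from_dict(json.loads(Path(path).read_text()))


def write_newick(params: UFAParams, path: str | Path,
                 labels: tuple[str, ...] | None = None) -> None:
    Path(path).write_text(
        to_newick(params.hierarchy, params.levels(), labels) + "\n"
    )
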