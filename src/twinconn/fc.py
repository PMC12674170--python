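"""Functional-connectivity matrices and their vectorized edge representation.

A subject's resting-state functional connectome is summarised as the matrix
of pairwise Pearson correlations between region-of-interest (ROI) BOLD time
series, normalised with the Fisher transformation ``z = atanh(r)``.  Runs
are averaged on the Fisher-z scale, and the strictly-lower triangle of the
averaged R x R matrix is unrolled into a 1-D *edge vector* of length
R(R-1)/2 — 35 778 edges for the canonical 268-node parcellation.

Conventions used everywhere in this package
-------------------------------------------
* Connectivity matrices are plain ``(R, R)`` float arrays, symmetric, with
  the (never consumed) diagonal stored as 0.
* Edge vectors are plain ``(R(R-1)/2,)`` float arrays ordered row-major
  over node pairs ``(i, j)`` with ``i > j``, 0-based:
  ``(1,0), (2,0), (2,1), (3,0), ...`` — i.e. ``numpy.tril_indices(R, -1)``
  order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesRun",
    "compute_fc_matrix",
    "average_runs",
    "vectorize_lower_triangle",
    "devectorize",
    "edge_count",
    "node_count_from_edges",
    "lower_triangle_pairs",
    "edge_index_to_node_pair",
    "node_pair_to_edge_index",
    "read_time_series",
    "read_fc_matrix",
]

#: Pearson correlations are clamped to +-(1 - R_CLAMP) before atanh.
R_CLAMP = 1e-12


@dataclass(frozen=True)
class TimeSeriesRun:
    """One resting-state run: ROI-averaged BOLD samples for one subject.

    ``data`` is ``(timepoints, R)``; at least two timepoints and two nodes,
    no missing values, and every column must have nonzero variance.
    """

    subject_id: str
    run_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                "time series must be (timepoints >= 2, nodes >= 2), "
                f"got shape {data.shape}"
            )
        if not np.isfinite(data).all():
            raise ValueError("time series contains missing/non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def node_count(self) -> int:
        return self.data.shape[1]


def compute_fc_matrix(ts: TimeSeriesRun) -> np.ndarray:
    """Fisher-z functional-connectivity matrix of one run.

    Entry ``(i, j)`` is ``atanh(r_ij)`` with ``r_ij`` the Pearson
    correlation between ROI time series ``i`` and ``j``; the diagonal is
    set to 0 by convention.  Off-diagonal correlations at exactly +-1 are
    clamped to ``+-(1 - 1e-12)`` with a warning; a zero-variance column is
    an error naming the node.
    """
    data = ts.data
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance time series for node(s) {dead.tolist()} "
            f"in subject {ts.subject_id!r} run {ts.run_id!r}"
        )
    r = np.corrcoef(data, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        warnings.warn(
            "perfectly (anti)correlated ROI pair; clamping r to +-(1-1e-12)",
            stacklevel=2,
        )
    np.clip(r, -1.0 + R_CLAMP, 1.0 - R_CLAMP, out=r)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    np.fill_diagonal(z, 0.0)
    return z


def average_runs(mats: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of Fisher-z matrices across runs.

    The acquisition protocol provides four runs per subject; fewer are
    accepted (handy for toy data) with a warning.
    """
    if len(mats) == 0:
        raise ValueError("no matrices to average")
    shapes = {np.asarray(m).shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"mismatched node counts across runs: {sorted(shapes)}")
    if len(mats) < 4:
        warnings.warn(
            f"averaging {len(mats)} run(s); the standard protocol has 4",
            stacklevel=2,
        )
    return np.mean(np.asarray(mats, dtype=float), axis=0)


def edge_count(node_count: int) -> int:
    """Number of unique edges R(R-1)/2."""
    return node_count * (node_count - 1) // 2


def node_count_from_edges(n_edges: int) -> int:
    """Inverse of :func:`edge_count`; errors if ``n_edges`` is not triangular."""
    r = int((1 + math.isqrt(1 + 8 * n_edges)) // 2)
    if edge_count(r) != n_edges:
        raise ValueError(f"{n_edges} is not R(R-1)/2 for any integer R")
    return r


@lru_cache(maxsize=32)
def lower_triangle_pairs(node_count: int) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) node indices of every edge, in edge-vector order."""
    return np.tril_indices(node_count, k=-1)


def vectorize_lower_triangle(mat: np.ndarray, *, atol: float = 1e-10) -> np.ndarray:
    """Unroll the strictly-lower triangle of a symmetric matrix.

    The inverse is :func:`devectorize`; the round trip is exact.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=atol, rtol=0):
        raise ValueError(f"matrix is asymmetric beyond tolerance {atol}")
    rows, cols = lower_triangle_pairs(mat.shape[0])
    return mat[rows, cols].copy()


def devectorize(vec: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix (diagonal 0) from an edge vector."""
    vec = np.asarray(vec, dtype=float)
    r = node_count_from_edges(vec.size)
    mat = np.zeros((r, r))
    rows, cols = lower_triangle_pairs(r)
    mat[rows, cols] = vec
    mat[cols, rows] = vec
    return mat


def edge_index_to_node_pair(k: int, node_count: int) -> tuple[int, int]:
    """Node pair ``(i, j)``, ``i > j``, of edge ``k`` (closed form)."""
    n_edges = edge_count(node_count)
    if not 0 <= k < n_edges:
        raise IndexError(f"edge index {k} out of range [0, {n_edges})")
    i = int((1 + math.isqrt(1 + 8 * k)) // 2)
    j = k - i * (i - 1) // 2
    return i, j


def node_pair_to_edge_index(i: int, j: int, node_count: int) -> int:
    """Edge-vector index of the unordered node pair ``{i, j}``."""
    if i == j:
        raise ValueError("diagonal entries are not edges")
    if not (0 <= i < node_count and 0 <= j < node_count):
        raise IndexError(f"node out of range for R={node_count}")
    if i < j:
        i, j = j, i
    return i * (i - 1) // 2 + j


# ---------------------------------------------------------------------------
# delimited-text ingestion

def read_time_series(
    path: str | Path, subject_id: str | None = None, run_id: str | None = None
) -> TimeSeriesRun:
    """Read one run of ROI time series from delimited text.

    Expects a header row of node ids and one row per timepoint; the
    delimiter (tab/comma/whitespace) is sniffed.  Defaults for the ids are
    taken from a ``<subject>_<run>`` file-stem pattern when not given.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    stem = path.stem
    if subject_id is None:
        subject_id = stem.rsplit("_", 1)[0] if "_" in stem else stem
    if run_id is None:
        run_id = stem.rsplit("_", 1)[1] if "_" in stem else "run1"
    return TimeSeriesRun(subject_id, run_id, df.to_numpy(float))


def read_fc_matrix(path: str | Path) -> np.ndarray:
    """Read a precomputed square Fisher-z matrix from delimited text."""
    mat = np.loadtxt(path, delimiter=None if str(path).endswith(".txt") else ",")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: not a square matrix (shape {mat.shape})")
    mat = np.asarray(mat, float)
    np.fill_diagonal(mat, 0.0)
    return mat
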