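"""Consensus edges across bootstrap models, node strengths, network tallies.

An edge counts toward the consensus of one bootstrap iteration only if it
was selected in *both* LOGOCV fold directions of that iteration; edges
appearing in strictly more than a given fraction of the B bootstrapped
models (50% by default: more than 500 of 1000) form the consensus set.
A node's *connectivity strength* is the number (or weight sum) of retained
edges incident to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .fc import edge_count, lower_triangle_pairs


@dataclass
class EdgeConsensus:
    """Per-edge selection counts over B bootstrap models."""

    counts: np.ndarray
    B: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.B:
            raise ValueError("counts must lie in [0, B]")

    @property
    def n_edges(self) -> int:
        return self.counts.size


def tally_edge_selection(selections: list, n_edges: int) -> EdgeConsensus:
    """Count, per edge, the iterations where both fold directions kept it.

    ``selections`` holds one ``(direction-1 indices, direction-2 indices)``
    tuple per bootstrap iteration.
    """
    counts = np.zeros(n_edges, dtype=int)
    for it, sel in enumerate(selections):
        if sel is None or len(sel) != 2 or any(s is None for s in sel):
            raise ValueError(f"iteration {it}: need selections for both directions")
        both = np.intersect1d(np.asarray(sel[0], int), np.asarray(sel[1], int))
        counts[both] += 1
    return EdgeConsensus(counts, len(selections))


def threshold_consensus(consensus: EdgeConsensus, fraction: float = 0.5) -> np.ndarray:
    """Edges appearing in strictly more than ``fraction * B`` models.

    The boundary is excluded: with B = 1000 and fraction 0.5 a count of
    exactly 500 does not survive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return np.flatnonzero(consensus.counts > fraction * consensus.B)


def node_strength(
    edges: np.ndarray,
    node_count: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Connectivity strength per node from a retained edge set.

    Unweighted: the count of retained edges incident to the node.  With
    ``weights`` (one per retained edge), the sum of absolute weights.
    """
    edges = np.asarray(edges, int)
    if edges.size and (edges.min() < 0 or edges.max() >= edge_count(node_count)):
        raise IndexError("edge index out of range for this node count")
    rows, cols = lower_triangle_pairs(node_count)
    w = np.ones(edges.size) if weights is None else np.abs(np.asarray(weights, float))
    strength = np.zeros(node_count)
    np.add.at(strength, rows[edges], w)
    np.add.at(strength, cols[edges], w)
    return strength


def top_k_nodes(
    strengths: np.ndarray, k: int, atlas: NetworkAtlas | None = None
) -> pd.DataFrame:
    """The k nodes of highest strength; ties broken by ascending node id."""
    strengths = np.asarray(strengths, float)
    if k > strengths.size:
        raise ValueError(f"k={k} exceeds node count {strengths.size}")
    order = np.lexsort((np.arange(strengths.size), -strengths))[:k]
    out = pd.DataFrame({"node": order, "strength": strengths[order]})
    if atlas is not None:
        out["network"] = atlas.node_labels[order]
        if atlas.node_coords is not None:
            out[["x", "y", "z"]] = atlas.node_coords[order]
    return out.reset_index(drop=True)


def network_tally(edges: np.ndarray, atlas: NetworkAtlas) -> pd.DataFrame:
    """Retained-edge counts by endpoint-network pair.

    Returns an upper-triangular table (networks x networks, canonical
    order); the diagonal holds within-network counts.  The table total
    equals the number of retained edges.
    """
    edges = np.asarray(edges, int)
    nets = atlas.networks
    pos = {n: i for i, n in enumerate(nets)}
    rows, cols = lower_triangle_pairs(atlas.node_count)
    table = np.zeros((len(nets), len(nets)), dtype=int)
    for e in edges:
        a = pos[atlas.node_labels[rows[e]]]
        b = pos[atlas.node_labels[cols[e]]]
        i, j = min(a, b), max(a, b)
        table[i, j] += 1
    return pd.DataFrame(table, index=nets, columns=nets)


def consensus_edge_table(
    edges: np.ndarray, consensus: EdgeConsensus, atlas: NetworkAtlas
) -> pd.DataFrame:
    """Exportable edge list: endpoints, their networks and the model count."""
    rows, cols = lower_triangle_pairs(atlas.node_count)
    edges = np.asarray(edges, int)
    return pd.DataFrame(
        {
            "node_i": rows[edges],
            "node_j": cols[edges],
            "network_i": atlas.node_labels[rows[edges]],
            "network_j": atlas.node_labels[cols[edges]],
            "count": consensus.counts[edges],
        }
    )
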