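"""Node-to-network atlas for the 268-ROI whole-brain parcellation.

The pipeline works on a fixed parcellation whose nodes are grouped into the
ten canonical resting-state networks used throughout the functional
connectome literature: medial frontal (MFN), frontoparietal (FPN), default
mode (DMN), motor (MOT), visual I (VISI), visual II (VISII), visual
association (VAN), limbic (LMB), basal ganglia (BG) and cerebellum (CRB).
For the canonical 268-node atlas the per-network node counts are
29/28/18/49/18/9/18/30/29/40.

An atlas here is just a per-node network label (plus optional MNI
coordinates); it never touches voxel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import edge_count, lower_triangle_pairs

#: Canonical network names, in the conventional reporting order.
NETWORK_NAMES: tuple[str, ...] = (
    "MFN", "FPN", "DMN", "MOT", "VISI", "VISII", "VAN", "LMB", "BG", "CRB",
)

#: Node counts per network for the canonical 268-node parcellation.
CANONICAL_NETWORK_SIZES: dict[str, int] = {
    "MFN": 29, "FPN": 28, "DMN": 18, "MOT": 49, "VISI": 18,
    "VISII": 9, "VAN": 18, "LMB": 30, "BG": 29, "CRB": 40,
}


@dataclass(frozen=True)
class NetworkAtlas:
    """Per-node network labels with optional MNI coordinates.

    Parameters
    ----------
    node_labels : numpy.ndarray of str, shape (R,)
        Network name of each node; every node carries exactly one label.
    node_coords : numpy.ndarray, shape (R, 3), optional
        MNI coordinates in millimetres.
    """

    node_labels: np.ndarray
    node_coords: np.ndarray | None = None
    _intra_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.node_labels, dtype=object)
        object.__setattr__(self, "node_labels", labels)
        if labels.ndim != 1 or labels.size < 2:
            raise ValueError("atlas needs a 1-D label array with >= 2 nodes")
        if self.node_coords is not None:
            coords = np.asarray(self.node_coords, dtype=float)
            if coords.shape != (labels.size, 3):
                raise ValueError(
                    f"node_coords must have shape ({labels.size}, 3), "
                    f"got {coords.shape}"
                )
            object.__setattr__(self, "node_coords", coords)

    @property
    def node_count(self) -> int:
        return int(self.node_labels.size)

    @property
    def networks(self) -> list[str]:
        """Distinct network names, canonical order first, extras appended."""
        present = set(self.node_labels.tolist())
        ordered = [n for n in NETWORK_NAMES if n in present]
        ordered += sorted(present - set(NETWORK_NAMES))
        return ordered

    def network_sizes(self) -> dict[str, int]:
        return {n: int(np.sum(self.node_labels == n)) for n in self.networks}

    def nodes_in(self, network: str) -> np.ndarray:
        self._check_network(network)
        return np.flatnonzero(self.node_labels == network)

    def _check_network(self, network: str) -> None:
        if network not in set(self.node_labels.tolist()):
            raise KeyError(
                f"unknown network {network!r}; valid names: {self.networks}"
            )


def intra_network_edge_indices(atlas: NetworkAtlas, network: str) -> np.ndarray:
    """Edge indices whose *both* endpoints lie in ``network``.

    Returns the sorted indices into the lower-triangle edge vector; for an
    m-node network there are m(m-1)/2 of them.
    """
    atlas._check_network(network)
    cached = atlas._intra_cache.get(network)
    if cached is not None:
        return cached
    rows, cols = lower_triangle_pairs(atlas.node_count)
    mask = (atlas.node_labels[rows] == network) & (atlas.node_labels[cols] == network)
    idx = np.flatnonzero(mask)
    atlas._intra_cache[network] = idx
    return idx


def canonical_atlas(coords: np.ndarray | None = None) -> NetworkAtlas:
    """The 268-node atlas with the canonical ten-network partition.

    Nodes are labelled in contiguous blocks in the canonical network order;
    real deployments should load the true node-to-network lookup with
    :func:`read_atlas` instead.
    """
    labels = np.concatenate(
        [np.repeat(name, CANONICAL_NETWORK_SIZES[name]) for name in NETWORK_NAMES]
    )
    assert labels.size == 268
    return NetworkAtlas(labels, coords)


def scaled_atlas(node_count: int) -> NetworkAtlas:
    """A reduced atlas that keeps all ten networks at ~canonical proportions.

    Used for desk-scale runs and simulations: the ``node_count`` nodes are
    split over the ten networks proportionally to the canonical sizes
    (largest-remainder apportionment, minimum two nodes per network so every
    network owns at least one intra-network edge).

    Requires ``node_count >= 20``.
    """
    if node_count >= 268:
        raise ValueError("scaled_atlas is for node counts below 268")
    if node_count < 2 * len(NETWORK_NAMES):
        raise ValueError("need at least two nodes per network (>= 20 nodes)")
    sizes = np.array([CANONICAL_NETWORK_SIZES[n] for n in NETWORK_NAMES], float)
    quota = sizes / sizes.sum() * node_count
    alloc = np.maximum(np.floor(quota).astype(int), 2)
    # largest-remainder fill / trim to hit node_count exactly
    while alloc.sum() < node_count:
        alloc[np.argmax(quota - alloc)] += 1
    while alloc.sum() > node_count:
        shrinkable = np.flatnonzero(alloc > 2)
        alloc[shrinkable[np.argmin((quota - alloc)[shrinkable])]] -= 1
    labels = np.concatenate(
        [np.repeat(name, k) for name, k in zip(NETWORK_NAMES, alloc)]
    )
    return NetworkAtlas(labels)


def inter_network_edge_count(atlas: NetworkAtlas) -> int:
    """Number of edges whose endpoints carry different labels."""
    intra = sum(
        len(intra_network_edge_indices(atlas, n)) for n in atlas.networks
    )
    return edge_count(atlas.node_count) - intra


def read_atlas(path: str | Path) -> NetworkAtlas:
    """Read an atlas table (columns ``node_id, network[, x, y, z]``)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.sort_values("node_id")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns) and df[["x", "y", "z"]].notna().all().all():
        coords = df[["x", "y", "z"]].to_numpy(float)
    return NetworkAtlas(df["network"].to_numpy(object), coords)


def write_atlas(atlas: NetworkAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {"node_id": np.arange(atlas.node_count), "network": atlas.node_labels}
    )
    if atlas.node_coords is not None:
        df[["x", "y", "z"]] = atlas.node_coords
    df.to_csv(path, index=False)
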