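"""Persistence image -> grid graph conversion for the attention layers.

Each pixel becomes a node (row-major order, matching ``flatten``); edges
connect grid neighbours (8-neighbourhood by default, 4 as option) and every
node carries a self-loop so that the attention softmax is defined even for a
hypothetical isolated node.  The graph structure depends only on the grid
shape, never on pixel values — all image content travels in the node
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .tda import PersistenceImage

__all__ = ["PIGraph", "grid_graph", "pi_to_graph", "flatten", "unflatten"]


@dataclass
class PIGraph:
    """Node features plus fixed grid adjacency.

    node_features: (N, F) with N = R*R in row-major pixel order.
    src/dst: directed edge endpoint arrays (each undirected neighbour pair
    appears in both directions; self-loops once), sorted by dst so that
    per-destination segments are contiguous.
    seg_ptr: (N+1,) segment offsets into src/dst for each destination node.
    """

    node_features: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    seg_ptr: np.ndarray
    grid_shape: tuple[int, int]
    # source-sorted view of the edge list, for scatter-by-source via reduceat
    src_order: np.ndarray = None
    src_seg_ptr: np.ndarray = None

    def __post_init__(self) -> None:
        if self.src_order is None:
            self.src_order = np.argsort(self.src, kind="stable")
            src_sorted = self.src[self.src_order]
            self.src_seg_ptr = np.searchsorted(
                src_sorted, np.arange(self.node_features.shape[0] + 1))

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.src.shape[0]


@lru_cache(maxsize=8)
def grid_graph(rows: int, cols: int, neighborhood: int = 8):
    """Directed edge arrays (src, dst, seg_ptr) of a grid with self-loops."""
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighborhood == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    src_list, dst_list = [], []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            src_list.append(i)
            dst_list.append(i)
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    src_list.append(rr * cols + cc)
                    dst_list.append(i)
    src = np.asarray(src_list, dtype=np.intp)
    dst = np.asarray(dst_list, dtype=np.intp)
    order = np.argsort(dst, kind="stable")
    src, dst = src[order], dst[order]
    n = rows * cols
    seg_ptr = np.searchsorted(dst, np.arange(n + 1))
    return src, dst, seg_ptr


def pi_to_graph(pi: PersistenceImage | np.ndarray, neighborhood: int = 8) -> PIGraph:
    """One node per pixel, grid-neighbour edges, pixel intensity as feature."""
    pixels = pi.pixels if isinstance(pi, PersistenceImage) else np.asarray(pi, float)
    if pixels.ndim != 2:
        raise ValueError("persistence image must be 2-D")
    rows, cols = pixels.shape
    src, dst, seg_ptr = grid_graph(rows, cols, neighborhood)
    feats = pixels.reshape(-1, 1).astype(float)
    return PIGraph(feats, src, dst, seg_ptr, (rows, cols))


def flatten(pi: PersistenceImage | np.ndarray) -> np.ndarray:
    """Row-major flatten of an R x R image to an (R*R, 1) column vector."""
    pixels = pi.pixels if isinstance(pi, PersistenceImage) else np.asarray(pi, float)
    return pixels.reshape(-1, 1)


def unflatten(vector: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of ``flatten``; errors if the length does not match the grid."""
    v = np.asarray(vector, dtype=float).ravel()
    rows, cols = grid_shape
    if v.shape[0] != rows * cols:
        raise ValueError(
            f"vector of length {v.shape[0]} cannot fill a {rows}x{cols} grid")
    return v.reshape(rows, cols)
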