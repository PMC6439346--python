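"""Connectivity graphs: edge selection and the three coloring methods.

A connectivity result is a square weight matrix over node positions
(NaN = no edge). Display is undirected: only the upper triangle is read,
and every edge is reported in canonical (i < j) order. Edges can be
colored by connectivity strength, by per-node connection count (the line
becomes a gradient between its endpoint colors), or manually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colors import ColorSpec, map_colors

__all__ = ["ConnectivityGraph", "select_edges", "node_counts", "color_edges"]


@dataclass
class ConnectivityGraph:
    """Node positions plus an undirected weight matrix.

    Parameters
    ----------
    pos : (n, 3) float array
        Node positions in mm.
    weights : (n, n) float array
        Edge weights; NaN marks an absent edge. Only the upper triangle
        (i < j) is read.
    select : (n, n) bool array, optional
        Additional mask; an edge is eligible only where True.
    """

    pos: np.ndarray
    weights: np.ndarray
    select: np.ndarray | None = None
    directed: bool = False

    def __post_init__(self) -> None:
        if self.directed:
            raise ValueError("directed connectivity is not supported")
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        if self.pos.shape[1] != 3:
            raise ValueError(f"pos must be (n, 3), got {self.pos.shape}")
        n = len(self.pos)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights must be ({n}, {n}), got {self.weights.shape}")
        if self.select is not None:
            self.select = np.asarray(self.select, dtype=bool)
            if self.select.shape != (n, n):
                raise ValueError(f"select must be ({n}, {n})")

    @property
    def n_nodes(self) -> int:
        return len(self.pos)


def select_edges(
    g: ConnectivityGraph, lo: float = -np.inf, hi: float = np.inf
) -> list[tuple[int, int, float]]:
    """Edges with finite weight in [lo, hi], as (i, j, weight), i < j.

    Reads the upper triangle only; applies the graph's ``select`` mask
    if present. The list is sorted by (i, j), so permuting the (ignored)
    lower triangle of a symmetric input never changes the result.
    """
    if lo > hi:
        raise ValueError(f"need lo <= hi, got ({lo}, {hi})")
    w = g.weights
    iu, ju = np.triu_indices(g.n_nodes, k=1)
    vals = w[iu, ju]
    keep = np.isfinite(vals) & (vals >= lo) & (vals <= hi)
    if g.select is not None:
        keep &= g.select[iu, ju]
    return [(int(i), int(j), float(v)) for i, j, v in zip(iu[keep], ju[keep], vals[keep])]


def node_counts(edges: list[tuple[int, int, float]], n: int) -> np.ndarray:
    """Degree of each node over a selected edge list.

    Satisfies the handshake identity: the degrees sum to twice the edge
    count.
    """
    deg = np.zeros(n, dtype=np.int64)
    for i, j, _ in edges:
        deg[i] += 1
        deg[j] += 1
    return deg


def color_edges(
    g: ConnectivityGraph,
    edges: list[tuple[int, int, float]],
    method: str = "strength",
    spec: ColorSpec | None = None,
    manual_color=(1.0, 0.0, 0.0, 1.0),
) -> np.ndarray:
    """Per-edge endpoint RGBA pairs, shape (n_edges, 2, 4).

    - ``strength``: both endpoints colored by the edge weight.
    - ``count``: endpoint k colored by node k's degree, so the renderer
      draws each line as a gradient between its endpoint colors.
    - ``manual``: both endpoints get ``manual_color``.
    """
    if method not in ("strength", "count", "manual"):
        raise ValueError(f"unknown coloring method {method!r}")
    n_edges = len(edges)
    out = np.empty((n_edges, 2, 4))
    if n_edges == 0:
        return out
    if method == "manual":
        out[:] = np.asarray(manual_color, dtype=float)
        return out
    if spec is None:
        raise ValueError(f"method {method!r} requires a ColorSpec")
    if method == "strength":
        cols = map_colors([w for _, _, w in edges], spec)
        out[:, 0] = cols
        out[:, 1] = cols
    else:  # count
        deg = node_counts(edges, g.n_nodes)
        cols = map_colors(deg.astype(float), spec)
        for e, (i, j, _) in enumerate(edges):
            out[e, 0] = cols[i]
            out[e, 1] = cols[j]
    return out
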