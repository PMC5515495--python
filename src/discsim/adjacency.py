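"""Delaunay neighbour graph with pruning, edge ages, and division repair.

Two cells are candidate neighbours when they share a Delaunay edge; the
edge is kept only if the centre distance does not exceed
``cutoff_factor * (r_i + r_j)``, which removes the spurious long edges that
the triangulation produces along the hull.  Every surviving edge carries
the time step at which the pair first became adjacent; edges younger than
a grace period are excluded from polarity read-outs (binding is not
gated — proteins are shared with *all* current neighbours).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError

DEFAULT_CUTOFF_FACTOR = 1.5
DEFAULT_GRACE_PERIOD = 30  # steps (minutes at dt = 1)

__all__ = [
    "delaunay_edges",
    "prune_edges",
    "pruned_edge_array",
    "NeighborGraph",
    "DEFAULT_CUTOFF_FACTOR",
    "DEFAULT_GRACE_PERIOD",
]


def _collinear_chain(points: np.ndarray) -> np.ndarray:
    """Degenerate fallback: connect consecutive points along their
    principal axis (the limit of the triangulation as points become
    collinear)."""
    centred = points - points.mean(axis=0)
    # principal direction via the larger-variance eigenvector
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    order = np.argsort(centred @ vt[0])
    return np.sort(np.column_stack([order[:-1], order[1:]]), axis=1)


def delaunay_edges(points) -> np.ndarray:
    """Delaunay edge set of a 2-D point cloud as a sorted (E, 2) array.

    Fewer than three points yield the complete graph; collinear inputs fall
    back to a nearest-chain along the shared line.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    if n == 2:
        return np.array([[0, 1]], dtype=np.int64)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return _collinear_chain(pts).astype(np.int64)
    s = tri.simplices
    pairs = np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    pairs = np.sort(pairs, axis=1)
    edges = np.unique(pairs, axis=0)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order].astype(np.int64)


def prune_edges(edges: np.ndarray, pos: np.ndarray, radii: np.ndarray,
                cutoff_factor: float = DEFAULT_CUTOFF_FACTOR) -> np.ndarray:
    """Drop edges whose centre distance exceeds cutoff * (r_i + r_j)."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.shape[0] == 0:
        return edges
    i, j = edges[:, 0], edges[:, 1]
    d = np.hypot(*(pos[j] - pos[i]).T)
    keep = d <= cutoff_factor * (radii[i] + radii[j])
    return edges[keep]


def pruned_edge_array(pos, radii,
                      cutoff_factor: float = DEFAULT_CUTOFF_FACTOR) -> np.ndarray:
    """Convenience: triangulate then prune in one call."""
    return prune_edges(delaunay_edges(pos), np.asarray(pos, float),
                       np.asarray(radii, float), cutoff_factor)


class NeighborGraph:
    """Pruned Delaunay adjacency with per-edge establishment steps."""

    def __init__(self, n_cells: int = 0):
        self.n_cells = int(n_cells)
        self.est: dict[tuple[int, int], int] = {}
        self._adj: dict[int, list[int]] | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def build(cls, pos, radii, step: int,
              cutoff_factor: float = DEFAULT_CUTOFF_FACTOR,
              prev: "NeighborGraph | None" = None,
              jitter=None) -> "NeighborGraph":
        """Triangulate + prune current positions; persisting pairs keep
        their establishment step from ``prev``, new pairs get ``step``."""
        pos = np.asarray(pos, dtype=float)
        if jitter is not None:
            pos = pos + jitter
        g = cls(n_cells=len(radii))
        edges = pruned_edge_array(pos, radii, cutoff_factor)
        old = prev.est if prev is not None else {}
        g.est = {(int(a), int(b)): old.get((int(a), int(b)), step)
                 for a, b in edges}
        return g

    # -- views ---------------------------------------------------------

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) sorted edge array (deterministic order)."""
        if not self.est:
            return np.empty((0, 2), dtype=np.int64)
        e = np.array(sorted(self.est), dtype=np.int64)
        return e

    def est_of(self, edges: np.ndarray) -> np.ndarray:
        return np.array([self.est[(int(a), int(b))] for a, b in edges],
                        dtype=np.int64)

    def _adjacency(self) -> dict[int, list[int]]:
        if self._adj is None:
            adj: dict[int, list[int]] = {}
            for a, b in self.est:
                adj.setdefault(a, []).append(b)
                adj.setdefault(b, []).append(a)
            self._adj = {k: sorted(v) for k, v in adj.items()}
        return self._adj

    def neighbors(self, cell_id: int) -> list[int]:
        if not (0 <= cell_id < self.n_cells):
            raise KeyError(f"unknown cell {cell_id}")
        return self._adjacency().get(cell_id, [])

    def mature_neighbors(self, cell_id: int, step: int,
                         grace_period: int = DEFAULT_GRACE_PERIOD) -> list[int]:
        """Neighbours adjacent for at least ``grace_period`` steps."""
        out = []
        for n in self.neighbors(cell_id):
            key = (cell_id, n) if cell_id < n else (n, cell_id)
            if step - self.est[key] >= grace_period:
                out.append(n)
        return out

    # -- mutation ------------------------------------------------------

    def _dirty(self):
        self._adj = None

    def add_edge(self, a: int, b: int, step: int) -> None:
        key = (a, b) if a < b else (b, a)
        if key[0] == key[1]:
            raise ValueError("self-edge")
        self.est.setdefault(key, step)
        self._dirty()

    def remove_edge(self, a: int, b: int) -> None:
        key = (a, b) if a < b else (b, a)
        self.est.pop(key, None)
        self._dirty()

    def update_after_division(self, mother_id: int, daughter_id: int,
                              pos: np.ndarray, radii: np.ndarray, step: int,
                              cutoff_factor: float = DEFAULT_CUTOFF_FACTOR,
                              ) -> dict[int, str]:
        """Locally re-triangulate {mother, daughter, mother's former
        neighbours} after a division.

        Former neighbours end up attached to the mother, the daughter, or
        both; spurious edges between two former neighbours are expunged
        (never added to the global graph).  The mother-daughter edge is
        established at ``step``; daughter-neighbour edges inherit the
        establishment step of the corresponding mother-neighbour edge.

        Returns a map former-neighbour id -> 'mother' | 'daughter' | 'both'
        (used to assign interface bonds to daughters).
        """
        self.n_cells = max(self.n_cells, daughter_id + 1)
        former = self.neighbors(mother_id)
        old_est = {n: self.est[(min(mother_id, n), max(mother_id, n))]
                   for n in former}
        local = [mother_id, daughter_id] + former
        lpos = pos[local]
        lrad = radii[local]
        ledges = pruned_edge_array(lpos, lrad, cutoff_factor)
        # translate to global ids, keeping only edges that touch a daughter
        keep_m, keep_d = set(), set()
        for a, b in ledges:
            ga, gb = local[a], local[b]
            if {ga, gb} == {mother_id, daughter_id}:
                continue
            if ga == mother_id or gb == mother_id:
                keep_m.add(gb if ga == mother_id else ga)
            elif ga == daughter_id or gb == daughter_id:
                keep_d.add(gb if ga == daughter_id else ga)
            # neighbour-neighbour edges: expunged (not reintegrated)
        for n in former:
            self.remove_edge(mother_id, n)
        assignment: dict[int, str] = {}
        for n in former:
            m_side, d_side = n in keep_m, n in keep_d
            if m_side:
                self.add_edge(mother_id, n, old_est[n])
                self.est[(min(mother_id, n), max(mother_id, n))] = old_est[n]
            if d_side:
                self.add_edge(daughter_id, n, old_est[n])
                self.est[(min(daughter_id, n), max(daughter_id, n))] = old_est[n]
            if m_side and d_side:
                assignment[n] = "both"
            elif d_side:
                assignment[n] = "daughter"
            else:
                # not adjacent to either in the local result: keep with mother
                if not m_side:
                    self.add_edge(mother_id, n, old_est[n])
                assignment[n] = "mother"
        self.add_edge(mother_id, daughter_id, step)
        self.est[(min(mother_id, daughter_id), max(mother_id, daughter_id))] = step
        self._dirty()
        return assignment
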