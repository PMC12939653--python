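"""Vascular graph container.

A vascular network is stored as a :class:`networkx.MultiGraph` (parallel
segments and self-loop rings are legitimate anatomy) with

* node attributes: ``pos_mm`` (tuple, physical coordinates of voxel centers),
  ``kind`` (``bifurcation`` / ``terminal`` / ``junction``);
* edge attributes: ``polyline_mm`` (N x ndim array of centerline points),
  ``length_mm``, ``diameter_mm``, ``confidence`` in [0, 1], ``conductance``,
  and ``index`` (deterministic insertion order used for tie-breaking).
"""

from __future__ import annotations

import numpy as np
import networkx as nx

__all__ = ["VascularGraph"]


class VascularGraph:
    """Nodes at bifurcations/terminals, edges = vessel segments."""

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.g = graph if graph is not None else nx.MultiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id, pos_mm, kind="junction"):
        self.g.add_node(node_id, pos_mm=tuple(float(c) for c in pos_mm), kind=kind)

    def add_edge(self, u, v, polyline_mm, diameter_mm, confidence=1.0,
                 conductance=None):
        polyline_mm = np.asarray(polyline_mm, dtype=float)
        length = float(np.sum(np.linalg.norm(np.diff(polyline_mm, axis=0), axis=1)))
        if u == v and length == 0.0:
            raise ValueError("self-loop with zero length is not allowed")
        if not (0.0 <= confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        key = self.g.add_edge(
            u, v,
            polyline_mm=polyline_mm,
            length_mm=length,
            diameter_mm=float(diameter_mm),
            confidence=float(confidence),
            conductance=conductance,
            index=self.g.number_of_edges(),
        )
        return key

    def refresh_kinds(self):
        """Re-derive node kinds from current degrees."""
        for n in self.g.nodes:
            d = self.g.degree(n)
            kind = "terminal" if d <= 1 else ("junction" if d == 2 else "bifurcation")
            self.g.nodes[n]["kind"] = kind

    # -- topology ---------------------------------------------------------
    @property
    def n_nodes(self):
        return self.g.number_of_nodes()

    @property
    def n_edges(self):
        return self.g.number_of_edges()

    def betti0(self) -> int:
        """Number of connected components."""
        if self.n_nodes == 0:
            return 0
        return nx.number_connected_components(self.g)

    def betti1(self) -> int:
        """Cycle rank |E| - |V| + #components."""
        return self.n_edges - self.n_nodes + self.betti0()

    # -- convenience ------------------------------------------------------
    def edges(self, data=True, keys=True):
        return list(self.g.edges(data=data, keys=keys))

    def edge_attrs(self):
        """List of edge attribute dicts in deterministic ``index`` order."""
        return sorted((d for *_, d in self.g.edges(data=True)),
                      key=lambda d: d["index"])

    def total_length_mm(self) -> float:
        return float(sum(d["length_mm"] for *_, d in self.g.edges(data=True)))

    def node_positions(self) -> dict:
        return {n: np.asarray(d["pos_mm"]) for n, d in self.g.nodes(data=True)}

    def centerline_points_mm(self, step_mm: float = 0.25) -> np.ndarray:
        """All edge polylines resampled to roughly uniform spacing."""
        pts = []
        for d in self.edge_attrs():
            pts.append(resample_polyline(d["polyline_mm"], step_mm))
        if not pts:
            return np.empty((0, 2))
        return np.vstack(pts)

    def copy(self) -> "VascularGraph":
        return VascularGraph(self.g.copy())

    def __repr__(self):
        return (f"VascularGraph(|V|={self.n_nodes}, |E|={self.n_edges}, "
                f"b0={self.betti0()}, b1={self.betti1()})")


def resample_polyline(poly: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arclength spacing."""
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        return poly
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return poly[:1]
    n = max(2, int(np.ceil(total / step_mm)) + 1)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, poly.shape[1]))
    for dim in range(poly.shape[1]):
        out[:, dim] = np.interp(t, s, poly[:, dim])
    return out
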