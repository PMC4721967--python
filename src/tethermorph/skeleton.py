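"""Skeleton tracing of detected molecules.

A retained object mask is reduced to its medial-axis skeleton and converted
to a graph whose nodes are endpoints and junctions and whose edges carry the
ordered pixel path between them, the physical path length in nm, and the
mean underlying height.  This automates contour tracing of single molecules
with a segmented-line tool: all downstream morphometry works on this graph.

Path lengths use the chain-code rule: an axial step counts one pixel size,
a diagonal step sqrt(2) pixel sizes.

Short terminal spurs (below ``spur_prune_nm``, default 6 nm — under the
tip-broadened width of the duplex, so true splay arms are never pruned) are
removed and the graph re-condensed.  A skeleton that remains too complex
(more than 2 independent cycles or more than 6 endpoints) is declared
untraceable; selection treats that as a rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize

from .topograph import Topograph

SQRT2 = math.sqrt(2.0)

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class PathError(ValueError):
    pass


class UntraceableError(Exception):
    """The skeleton cannot be reduced to a single-molecule anatomy."""


def path_length(path: np.ndarray, pixel_size_nm: float) -> float:
    """Physical length of an ordered 8-connected pixel path.

    Each step contributes ``pixel_size_nm`` if axial and ``sqrt(2) *
    pixel_size_nm`` if diagonal.  Non-adjacent consecutive pixels raise
    :class:`PathError`.
    """
    path = np.asarray(path)
    if path.ndim != 2 or len(path) < 2:
        raise PathError("path must contain at least 2 pixels")
    d = np.abs(np.diff(path.astype(int), axis=0))
    if (d.max(axis=1) != 1).any():
        i = int(np.argmax(d.max(axis=1) != 1))
        raise PathError(f"non-adjacent pixels at path step {i}: {path[i]} -> {path[i+1]}")
    diag = (d.min(axis=1) == 1)
    return float((np.where(diag, SQRT2, 1.0)).sum() * pixel_size_nm)


@dataclass
class SkeletonGraph:
    """Condensed skeleton of one molecule.

    ``graph`` is a :class:`networkx.MultiGraph` whose nodes are (row, col)
    pixel tuples with a ``kind`` attribute (``endpoint`` | ``junction`` |
    ``anchor``) and whose edges carry ``path`` (ordered (n, 2) int array),
    ``length_nm`` and ``mean_height_nm``.
    """

    graph: nx.MultiGraph
    pixel_size_nm: float
    molecule_id: int = -1
    meta: dict = field(default_factory=dict)

    @property
    def endpoints(self) -> list[tuple[int, int]]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "endpoint"]

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "junction"]

    def n_cycles(self) -> int:
        g = self.graph
        return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)

    def total_length_nm(self) -> float:
        return float(sum(d["length_nm"] for *_e, d in self.graph.edges(data=True)))


def _pixel_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pix)
    for (r, c) in pix:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pix and (q, (r, c)) not in g.edges:
                g.add_edge((r, c), q)
    return g


def _condense(pg: nx.Graph, heights: np.ndarray, pixel_size_nm: float) -> nx.MultiGraph:
    """Collapse degree-2 chains of the pixel graph into path edges.

    Adjacent non-chain pixels (8-connected skeletons produce small clusters
    of mutually adjacent junction pixels) are merged into a single graph
    node, represented by one deterministic member pixel; intra-cluster
    adjacencies are ignored so they cannot masquerade as cycles.
    """
    cg = nx.MultiGraph()
    node_px = {p for p in pg.nodes if pg.degree(p) != 2}
    rep: dict[tuple, tuple] = {}
    to_rep: dict[tuple, list] = {}      # member -> pixel path rep..member
    for comp in nx.connected_components(pg.subgraph(node_px)):
        r = min(comp)
        is_junction = len(comp) > 1 or any(pg.degree(p) >= 3 for p in comp)
        cg.add_node(r, kind="junction" if is_junction else "endpoint")
        sub = pg.subgraph(comp)
        paths = nx.single_source_shortest_path(sub, r)
        for p in comp:
            rep[p] = r
            to_rep[p] = paths.get(p, [p])

    covered: set[tuple] = set()

    def add_edge(path: list) -> None:
        # the measured length comes from the walked chain only (junction
        # cluster pixels are shared between edges and must not be counted
        # into each of them), floored by the straight-line distance between
        # the representative nodes so path length >= chord always holds;
        # the stored pixel path is extended through the clusters so its
        # ends coincide with the node coordinates
        ln = path_length(np.array(path), pixel_size_nm)
        u, v = rep[path[0]], rep[path[-1]]
        ln = max(ln, math.hypot(u[0] - v[0], u[1] - v[1]) * pixel_size_nm)
        head = to_rep[path[0]]
        tail = to_rep[path[-1]]
        if len(head) > 1 or len(tail) > 1:
            path = head[:-1] + list(map(tuple, path)) + tail[-2::-1]
        arr = np.array(path)
        covered.update(map(tuple, path))
        if u == v and ln < 3 * pixel_size_nm:
            return              # pixel-scale loop on one junction cluster
        cg.add_edge(u, v, path=arr, length_nm=ln,
                    mean_height_nm=float(heights[arr[:, 0], arr[:, 1]].mean()))

    visited_mid: set[tuple] = set()
    visited_pair: set[frozenset] = set()
    for p in node_px:
        for q in pg.neighbors(p):
            if q in node_px:
                if rep[q] != rep[p]:
                    key = frozenset((p, q))
                    if key not in visited_pair:
                        visited_pair.add(key)
                        add_edge([p, q])
                continue
            if q in visited_mid:
                continue
            path = [p, q]
            prev, cur = p, q
            while cur not in node_px:
                visited_mid.add(cur)
                nbrs = [x for x in pg.neighbors(cur) if x != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            add_edge(path)
    # components that are pure cycles (every pixel degree 2) have no nodes yet
    leftover = set(pg.nodes) - covered - node_px
    while leftover:
        start = min(leftover)  # deterministic anchor
        cycle = [start]
        prev, cur = None, start
        while True:
            nbrs = [q for q in pg.neighbors(cur) if q != prev]
            nxt = nbrs[0] if nbrs else None
            if nxt is None or nxt == start:
                break
            cycle.append(nxt)
            prev, cur = cur, nxt
        cycle.append(start)
        arr = np.array(cycle)
        cg.add_node(start, kind="anchor")
        cg.add_edge(start, start, path=arr,
                    length_nm=path_length(arr, pixel_size_nm),
                    mean_height_nm=float(heights[arr[:, 0], arr[:, 1]].mean()))
        leftover -= set(cycle)
    return cg


def _merge_degree2(cg: nx.MultiGraph) -> nx.MultiGraph:
    """Merge chains through nodes that have become degree-2 after pruning."""
    g = cg.copy()
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 2 and g.number_of_edges(n, n) == 0:
                edges = list(g.edges(n, keys=True, data=True))
                if len(edges) != 2:
                    continue
                (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                o1 = v1 if u1 == n else u1
                o2 = v2 if u2 == n else u2

                def _near(pix, node):
                    return max(abs(int(pix[0]) - node[0]), abs(int(pix[1]) - node[1]))
                p1 = d1["path"] if _near(d1["path"][-1], n) <= _near(d1["path"][0], n) \
                    else d1["path"][::-1]
                p2 = d2["path"] if _near(d2["path"][0], n) <= _near(d2["path"][-1], n) \
                    else d2["path"][::-1]
                newp = np.concatenate([p1, p2[1:]])
                w1, w2 = len(d1["path"]), len(d2["path"])
                mh = (d1["mean_height_nm"] * w1 + d2["mean_height_nm"] * w2) / (w1 + w2)
                g.remove_edge(u1, v1, k1)
                g.remove_edge(u2, v2, k2)
                g.remove_node(n)
                g.add_edge(o1, o2, path=newp,
                           length_nm=d1["length_nm"] + d2["length_nm"],
                           mean_height_nm=mh)
                changed = True
                break
    # refresh node kinds
    for n in g.nodes:
        g.nodes[n]["kind"] = "endpoint" if g.degree(n) <= 1 else (
            "junction" if g.degree(n) >= 3 else g.nodes[n].get("kind", "anchor"))
    return g


def _prune_spurs(cg: nx.MultiGraph, spur_prune_nm: float) -> nx.MultiGraph:
    g = cg.copy()
    while True:
        leaves = [(u, v, k, d) for u, v, k, d in g.edges(keys=True, data=True)
                  if (g.degree(u) == 1 or g.degree(v) == 1)
                  and u != v and d["length_nm"] < spur_prune_nm]
        if not leaves:
            break
        # never prune the last edge of a component
        pruned_any = False
        for u, v, k, d in sorted(leaves, key=lambda e: e[3]["length_nm"]):
            if not g.has_edge(u, v, k):
                continue
            comp_edges = g.subgraph(nx.node_connected_component(g, u)).number_of_edges()
            if comp_edges <= 1:
                continue
            leaf = u if g.degree(u) == 1 else v
            g.remove_edge(u, v, k)
            if g.degree(leaf) == 0:
                g.remove_node(leaf)
            pruned_any = True
        if not pruned_any:
            break
        g = _merge_degree2(g)
    return _merge_degree2(g)


def skeletonize_molecule(mask: np.ndarray, topo: Topograph,
                         molecule_id: int = -1,
                         spur_prune_nm: float = 6.0) -> SkeletonGraph:
    """Reduce a molecule mask to a pruned skeleton graph.

    Raises :class:`UntraceableError` if, after spur pruning, the skeleton
    has more than 2 independent cycles or more than 6 endpoints, or is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != topo.heights.shape:
        raise ValueError("mask and topograph shapes differ")
    skel = skeletonize(mask)
    if skel.sum() < 2:
        raise UntraceableError("skeleton vanished")
    pg = _pixel_graph(skel)
    cg = _condense(pg, topo.heights, topo.pixel_size_nm)
    cg = _prune_spurs(cg, spur_prune_nm)
    sg = SkeletonGraph(cg, topo.pixel_size_nm, molecule_id)
    if nx.number_connected_components(cg) > 1:
        # keep the largest component (pruning cannot disconnect, but a mask
        # with separated islands can skeletonize to several pieces)
        comps = sorted(nx.connected_components(cg), key=lambda c: -sum(
            d["length_nm"] for *_e, d in cg.subgraph(c).edges(data=True)))
        minor_len = sum(d["length_nm"] for comp in comps[1:]
                        for *_e, d in cg.subgraph(comp).edges(data=True))
        if minor_len > spur_prune_nm:
            raise UntraceableError("skeleton splits into multiple components")
        sg = SkeletonGraph(cg.subgraph(comps[0]).copy(), topo.pixel_size_nm, molecule_id)
    if sg.n_cycles() > 2:
        raise UntraceableError(f"{sg.n_cycles()} independent cycles")
    if len(sg.endpoints) > 6:
        raise UntraceableError(f"{len(sg.endpoints)} endpoints")
    return sg
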