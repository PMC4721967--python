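"""Structural-feature identification and 8-segment morphometry.

A traced molecule of a dimeric coiled-coil tether decomposes into at most
eight measurable segments, indexed from the N terminus:

====  =======================================
X1/X2 the two N-terminal splay arms (0 if the N end is not splayed)
X3    duplex stalk from the N end (or N splay junction) to the bubble
X4/X5 the two strands of the central unwinding bubble (0 if absent)
X6    duplex stalk from the bubble to the C end
X7/X8 the two C-terminal splay arms (0 if the C end is not splayed)
====  =======================================

A bubble-free molecule stores its whole stalk in X3 (X6 = 0).  Paired
features are averaged wherever a single per-molecule length is needed, so
the total length is (X1+X2)/2 + X3 + (X4+X5)/2 + X6 + (X7+X8)/2.

Identification is topological: the unique skeleton cycle (if any) is the
bubble and its two parallel paths are the strands; terminal edge pairs
sharing a junction are splay arms.  The N end is the end whose terminal
region is taller (the GFP cap exceeds the GRIP-domain cap); when the height
difference is below a declared tie threshold the molecule is kept but
flagged orientation-ambiguous and orientation-dependent metrics are
withheld.  An antibody label is an off-backbone blob exceeding a height
threshold, located by projection onto the traced backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .skeleton import SkeletonGraph, UntraceableError, path_length
from .topograph import Topograph


@dataclass
class SegmentLengths:
    """The X1..X8 segment decomposition of one molecule, in nm (0 = absent)."""

    x1: float = 0.0
    x2: float = 0.0
    x3: float = 0.0
    x4: float = 0.0
    x5: float = 0.0
    x6: float = 0.0
    x7: float = 0.0
    x8: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < 0 for v in vals):
            raise ValueError(f"segment lengths must be >= 0, got {vals}")
        for a, b, what in ((self.x1, self.x2, "N-splay arms"),
                           (self.x4, self.x5, "bubble strands"),
                           (self.x7, self.x8, "C-splay arms")):
            if (a > 0) != (b > 0):
                raise ValueError(f"{what} must both be present or both absent")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.x1, self.x2, self.x3, self.x4,
                self.x5, self.x6, self.x7, self.x8)

    @property
    def has_bubble(self) -> bool:
        return self.x4 > 0

    @property
    def n_splayed(self) -> bool:
        return self.x1 > 0

    @property
    def c_splayed(self) -> bool:
        return self.x7 > 0


@dataclass
class End:
    """One terminus of the molecule: a splay junction with two arms, or a
    plain backbone endpoint."""

    node: tuple[int, int]                 # pixel (row, col) of junction/terminus
    splayed: bool
    arm_lengths_nm: tuple[float, float] = (0.0, 0.0)
    arm_tip_nodes: tuple = ()
    tip_height_nm: float = 0.0


@dataclass
class Anatomy:
    """Annotated anatomy of one traced molecule, oriented N to C."""

    molecule_id: int
    n_end: End
    c_end: End
    stalk_n_nm: float                     # N end to bubble (whole stalk if no bubble)
    stalk_c_nm: float                     # bubble to C end (0 if no bubble)
    bubble_strands_nm: tuple[float, float]  # (0, 0) if no bubble
    orientation_ambiguous: bool
    pixel_size_nm: float
    # ordered (kind, pixel path, metric length) from N to C along the stalk;
    # bubble contributes both strand paths sharing one averaged metric length
    backbone_path: list[tuple[str, np.ndarray, float]] = field(default_factory=list)
    antibody_rel: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def has_bubble(self) -> bool:
        return self.bubble_strands_nm[0] > 0

    def backbone_length_nm(self) -> float:
        """Traced path length between the two end nodes (arms excluded)."""
        seen = set()
        total = 0.0
        for kind, _p, ln in self.backbone_path:
            if kind == "bubble":
                if "bubble" in seen:
                    continue
                seen.add("bubble")
            total += ln
        return total

    def end_to_end_nm(self) -> float:
        a, b = self.n_end.node, self.c_end.node
        return math.hypot(a[0] - b[0], a[1] - b[1]) * self.pixel_size_nm


def _terminal_height(topo: Topograph, node: tuple[int, int], r_px: int = 3) -> float:
    r0, c0 = node
    h = topo.heights
    sl = h[max(0, r0 - r_px):r0 + r_px + 1, max(0, c0 - r_px):c0 + r_px + 1]
    return float(sl.max()) if sl.size else 0.0


def _orient_path(path: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Orient a pixel path so the end nearest ``start`` comes first (node
    coordinates are cluster representatives, so exact equality can fail)."""
    d0 = max(abs(int(path[0][0]) - start[0]), abs(int(path[0][1]) - start[1]))
    d1 = max(abs(int(path[-1][0]) - start[0]), abs(int(path[-1][1]) - start[1]))
    return path if d0 <= d1 else path[::-1]


def identify_features(sg: SkeletonGraph, topo: Topograph,
                      mask: np.ndarray | None = None, *,
                      bubble_min_nm: float = 8.0,
                      height_tie_nm: float = 0.25,
                      antibody_height_min_nm: float = 3.2,
                      spur_forgive_nm: float = 12.0) -> Anatomy:
    """Parse a skeleton graph into the canonical tether anatomy.

    Raises :class:`UntraceableError` when the graph cannot be reduced to
    (optional N splay) - stalk - (optional bubble) - stalk - (optional C
    splay): e.g. self-crossing loops, multi-junction cycles, or junctions
    with unexplained branches.
    """
    g: nx.MultiGraph = sg.graph.copy()
    if sg.n_cycles() > 1:
        raise UntraceableError("more than one cycle")
    if len(sg.endpoints) > 4:
        raise UntraceableError("more than 4 endpoints")
    if list(nx.selfloop_edges(g)):
        raise UntraceableError("self-crossing loop")

    # ---- bubble: the unique cycle must be a pair of parallel edges
    bubble_strands: tuple[float, float] = (0.0, 0.0)
    strand_paths: list[np.ndarray] = []
    bubble_nodes: tuple | None = None
    if sg.n_cycles() == 1:
        pair = None
        for u, v in {tuple(sorted(e[:2])) for e in g.edges()}:
            if g.number_of_edges(u, v) == 2:
                pair = (u, v)
            elif g.number_of_edges(u, v) > 2:
                raise UntraceableError("triple parallel edges")
        if pair is None:
            raise UntraceableError("cycle through multiple junctions")
        u, v = pair
        datas = [d for _k, d in g[u][v].items()]
        lengths = sorted((d["length_nm"] for d in datas), reverse=True)
        if sum(lengths) < bubble_min_nm:
            # pixel-scale loop: treat as stalk of the averaged length
            keep = datas[0]
            g.remove_edge(u, v)
            g.remove_edge(u, v)
            g.add_edge(u, v, path=keep["path"],
                       length_nm=sum(lengths) / 2.0,
                       mean_height_nm=keep["mean_height_nm"])
        else:
            bubble_strands = (lengths[0], lengths[1])
            bubble_nodes = (u, v)
            strand_paths = [np.asarray(d["path"]) for d in datas]
            strand_lens = [d["length_nm"] for d in datas]
            avg = sum(lengths) / 2.0
            g.remove_edge(u, v)
            g.remove_edge(u, v)
            g.add_edge(u, v, path=strand_paths[0], length_nm=avg,
                       mean_height_nm=datas[0]["mean_height_nm"], bubble=True)

    # ---- interior spurs: junctions with exactly one short leaf branch
    def leaf_edges_at(j):
        out = []
        for u, v, k, d in g.edges(j, keys=True, data=True):
            other = v if u == j else u
            if g.degree(other) == 1:
                out.append((u, v, k, d, other))
        return out

    changed = True
    while changed:
        changed = False
        for j in [n for n in g.nodes if g.degree(n) >= 3]:
            leaves = leaf_edges_at(j)
            n_others = g.degree(j) - len(leaves)
            # a short, tall leaf is an antibody-blob spur, not a splay arm
            # (the blob stands ~2x above the duplex ridge)
            for u, v, k, d, other in leaves:
                if (d["length_nm"] < spur_forgive_nm and not d.get("bubble")
                        and d["mean_height_nm"] >= 0.9 * antibody_height_min_nm
                        and (len(leaves) >= 3 or n_others >= 2)):
                    g.remove_edge(u, v, k)
                    g.remove_node(other)
                    _merge_through(g, j)
                    changed = True
                    break
            if changed:
                break
            if n_others >= 2 and len(leaves) == 1:
                u, v, k, d, other = leaves[0]
                if d["length_nm"] < spur_forgive_nm and not d.get("bubble"):
                    g.remove_edge(u, v, k)
                    g.remove_node(other)
                    _merge_through(g, j)
                    changed = True
                    break
                raise UntraceableError("long unexplained side branch")

    # ---- terminal structures
    junctions = [n for n in g.nodes if g.degree(n) >= 3]
    if any(g.degree(n) > 3 for n in junctions):
        raise UntraceableError("junction of degree > 3 (crossing?)")
    if len(junctions) > 2:
        raise UntraceableError(f"{len(junctions)} junctions")
    ends: list[End] = []
    claimed: set = set()
    claimed_tips: set = set()
    for j in junctions:
        leaves = leaf_edges_at(j)
        if len(leaves) == 3:
            # single-splay star: the two shortest branches are the arms,
            # the longest is the stalk to the (plain) far end
            arms = sorted(leaves, key=lambda e: e[3]["length_nm"])[:2]
        elif len(leaves) == 2:
            arms = leaves
        else:
            raise UntraceableError("junction with unexplained branch pattern")
        arm_l = tuple(sorted((b[3]["length_nm"] for b in arms), reverse=True))
        tip_nodes = tuple(b[4] for b in arms)
        for b in arms:
            claimed.add((tuple(sorted((b[0], b[1]))), b[2]))
            claimed_tips.add(b[4])
        ends.append(End(j, True, (arm_l[0], arm_l[1]), tip_nodes))
    for n in g.nodes:
        if g.degree(n) == 1 and n not in claimed_tips:
            ends.append(End(n, False))
    if len(ends) != 2:
        raise UntraceableError(f"found {len(ends)} molecule ends")

    # ---- stalk path between end nodes
    a, b = ends[0].node, ends[1].node
    simple = nx.Graph()
    for u, v, k, d in g.edges(keys=True, data=True):
        if (tuple(sorted((u, v))), k) in claimed:
            continue
        if simple.has_edge(u, v):   # should not happen after bubble collapse
            raise UntraceableError("duplicate stalk edges")
        simple.add_edge(u, v, key=k, **d)
    try:
        node_path = nx.shortest_path(simple, a, b)
    except (nx.NetworkXNoPath, nx.NodeNotFound) as e:
        raise UntraceableError(f"no stalk path between ends: {e}")
    if len(node_path) == 1:
        raise UntraceableError("coincident molecule ends")

    segs: list[tuple[str, np.ndarray, float]] = []
    stalk_before = 0.0
    stalk_after = 0.0
    seen_bubble = False
    bubble_entry = None
    for u, v in zip(node_path[:-1], node_path[1:]):
        d = simple[u][v]
        p = _orient_path(np.asarray(d["path"]), u)
        if d.get("bubble"):
            seen_bubble = True
            bubble_entry = u
            avg = d["length_nm"]
            for sp in strand_paths:
                segs.append(("bubble", _orient_path(sp, u), avg))
        else:
            segs.append(("stalk", p, d["length_nm"]))
            if seen_bubble:
                stalk_after += d["length_nm"]
            else:
                stalk_before += d["length_nm"]
    if bubble_nodes is not None and not seen_bubble:
        raise UntraceableError("bubble not on the stalk path")

    # ---- bubble vertex reconstruction
    # The skeleton fuses the two strands a little inside the true bubble
    # vertices (they merge once closer than the mask can resolve), so raw
    # cycle strands are short and the flanking stalks long by the same
    # amount.  Reconstruct the lens analytically from the junction-to-
    # junction chord and each strand's sagitta, assuming circular-arc
    # strands, and move the reclaimed length from the stalks into the
    # strands.
    if bubble_nodes is not None:
        oriented = [_orient_path(sp, bubble_entry) for sp in strand_paths]
        hole_chord = _bubble_hole_chord(mask, oriented) if mask is not None else None
        corr = _lens_reconstruction(oriented, strand_lens, sg.pixel_size_nm,
                                    hole_chord_px=hole_chord)
        if corr is not None:
            lens, lj = corr
            stalk_before = max(0.0, stalk_before - lj)
            stalk_after = max(0.0, stalk_after - lj)
        else:
            lens = list(strand_lens)
        lens = [max(v, 1.0) for v in lens]
        bubble_strands = (max(lens), min(lens))
        avg_new = sum(lens) / 2.0
        segs = [(k, p, avg_new if k == "bubble" else ln) for k, p, ln in segs]

    # ---- orientation by terminal cap height
    for e in ends:
        tips = e.arm_tip_nodes if e.splayed else (e.node,)
        e.tip_height_nm = max(_terminal_height(topo, t) for t in tips)
    ambiguous = abs(ends[0].tip_height_nm - ends[1].tip_height_nm) < height_tie_nm
    if not ambiguous and ends[1].tip_height_nm > ends[0].tip_height_nm:
        ends = [ends[1], ends[0]]
        stalk_before, stalk_after = stalk_after, stalk_before
        segs = [(k, p[::-1], ln) for k, p, ln in reversed(segs)]
    if not bubble_strands[0]:
        stalk_before, stalk_after = stalk_before + stalk_after, 0.0

    anat = Anatomy(
        molecule_id=sg.molecule_id, n_end=ends[0], c_end=ends[1],
        stalk_n_nm=stalk_before, stalk_c_nm=stalk_after,
        bubble_strands_nm=bubble_strands,
        orientation_ambiguous=ambiguous,
        pixel_size_nm=sg.pixel_size_nm,
        backbone_path=segs)

    # ---- antibody blob
    if mask is not None:
        anat.antibody_rel = _find_antibody(anat, topo, mask, antibody_height_min_nm)
    return anat


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([1.0, 0.0])


def _bubble_hole_chord(mask: np.ndarray, strand_paths) -> float | None:
    """Extent (px) of the bubble's enclosed background hole along the
    junction-to-junction direction, or None when no usable hole exists.

    Hole tips are area landmarks, insensitive to the orientation-dependent
    chain-code errors that displace skeleton junctions, so they anchor the
    lens reconstruction much more stably than the junctions themselves.
    """
    from scipy import ndimage as ndi
    pts = np.concatenate(strand_paths)
    r0, c0 = (int(max(v, 0)) for v in pts.min(axis=0) - 2)
    r1, c1 = (int(v) for v in pts.max(axis=0) + 3)
    sub = mask[r0:r1, c0:c1]
    filled = ndi.binary_fill_holes(sub)
    holes, n = ndi.label(filled & ~sub)
    if n == 0:
        return None
    j_in = strand_paths[0][0].astype(float)
    j_out = strand_paths[0][-1].astype(float)
    d = j_out - j_in
    nd = float(np.linalg.norm(d))
    if nd == 0:
        return None
    u = d / nd
    mid = (j_in + j_out) / 2.0 - (r0, c0)
    best, best_d = None, np.inf
    for i in range(1, n + 1):
        hp = np.argwhere(holes == i).astype(float)
        cdist = float(np.linalg.norm(hp.mean(axis=0) - mid))
        if cdist < best_d:
            best, best_d = hp, cdist
    if best is None or best_d > max(nd, 4.0):
        return None
    proj = best @ u
    return float(proj.max() - proj.min() + 1.0)


def _lens_reconstruction(paths_in_first, raw_lens_nm,
                         pixel_size_nm: float,
                         hole_chord_px: float | None = None,
                         merge_separation_px: float = 1.1,
                         hole_separation_px: float = 2.05,
                         max_extend_px: float = 8.0,
                         max_reclaim_px: float = 4.0,
                         ) -> tuple[list[float], float] | None:
    """Reconstruct true bubble strand lengths from the fused skeleton.

    Model: the two strands are circular arcs over a common chord (a lens).
    The skeleton junctions sit where the inter-strand separation drops
    below what the mask resolves — inside the true vertices — so the raw
    cycle strands are short and the flanking stalks long.  The chord is
    anchored on the enclosed hole's tips when available: the hole pinches
    out where the centreline separation equals one background pixel plus
    the rendered ridge width, an instrument constant calibrated at 2.05 px
    on synthetic lens targets (strand lengths 15-27 nm, orientations 0-70
    degrees, sub-pixel phases).  Without a hole it falls back to the
    junction chord (junction merge separation 1.1 px, calibrated on
    Y-junction targets).  Given the anchor and each strand's sagitta,
    iterate the vertex extension t such that the modelled separation at
    distance t from the vertex equals the anchor separation, then report
    each strand's full arc length.  Returns (strand lengths nm,
    per-junction stalk reclaim nm), or None for degenerate geometry (raw
    skeleton lengths then stand).
    """
    j_in = paths_in_first[0][0].astype(float)
    j_out = paths_in_first[0][-1].astype(float)
    chord_raw = float(np.linalg.norm(j_out - j_in))
    if chord_raw < 2.0:
        return None
    anchors = [(chord_raw, merge_separation_px)]
    if hole_chord_px is not None and hole_chord_px >= 2.0:
        anchors.append((hole_chord_px, hole_separation_px))
    u = (j_out - j_in) / chord_raw
    nvec = np.array([-u[1], u[0]])
    sagittas = []
    for p in paths_in_first:
        rel = p.astype(float) - j_in
        off = rel @ nvec
        xs = rel @ u
        near_mid = np.abs(xs - chord_raw / 2) < max(1.5, chord_raw / 6)
        h = float(np.mean(np.abs(off[near_mid]))) if near_mid.any() \
            else float(np.max(np.abs(off)))
        if h < 0.3 or h > 8.0:
            return None
        sagittas.append(h)

    def radius(h: float, c: float) -> float:
        return (h * h + (c / 2) * (c / 2)) / (2 * h)

    def separation(x: float, c: float, radii) -> float:
        s = 0.0
        for h, r in zip(sagittas, radii):
            d2 = r * r - (c / 2 - x) ** 2
            s += math.sqrt(max(d2, 0.0)) - (r - h)
        return s

    def reconstruct(anchor_chord: float, anchor_sep: float):
        t = 0.0
        for _ in range(6):
            c = anchor_chord + 2 * t
            radii = [radius(h, c) for h in sagittas]
            # bisect separation(x) == anchor separation on x in [0, c/2]
            lo, hi = 0.0, c / 2
            if separation(hi, c, radii) <= anchor_sep:
                return None                 # bubble too slim to model
            for _b in range(40):
                mid = 0.5 * (lo + hi)
                if separation(mid, c, radii) < anchor_sep:
                    lo = mid
                else:
                    hi = mid
            t = min(0.5 * (lo + hi), max_reclaim_px)
        c = anchor_chord + 2 * t
        out = []
        for h, raw in zip(sagittas, raw_lens_nm):
            r = radius(h, c)
            a = math.asin(min(c / (2 * r), 1.0))
            if h > c / 2:                   # more than half-circle bulge
                a = math.pi - a
            arc_px = 2 * r * a
            raw_px = raw / pixel_size_nm
            arc_px = float(np.clip(arc_px, 0.85 * raw_px, raw_px + max_extend_px))
            out.append(arc_px * pixel_size_nm)
        # stalk length reclaimed at each junction: from the junction to the
        # reconstructed vertex (non-negative; junctions can sit outside the
        # vertices at oblique orientations)
        lj = float(np.clip((c - chord_raw) / 2, 0.0, max_reclaim_px))
        return out, lj * pixel_size_nm

    # both anchors overestimate when their landmark is displaced outward;
    # taking the smaller reconstruction suppresses the orientation-dependent
    # outward displacement of whichever landmark happens to be worse
    candidates = [r for r in (reconstruct(c0, s0) for c0, s0 in anchors)
                  if r is not None]
    if not candidates:
        return None
    return min(candidates, key=lambda r: sum(r[0]))


def _merge_through(g: nx.MultiGraph, n) -> None:
    """Merge the two edges through a node that has dropped to degree 2."""
    if g.degree(n) != 2 or g.number_of_edges(n, n):
        return
    (u1, v1, k1, d1), (u2, v2, k2, d2) = list(g.edges(n, keys=True, data=True))
    if d1.get("bubble") or d2.get("bubble"):
        return                      # keep the bubble pseudo-edge intact
    o1 = v1 if u1 == n else u1
    o2 = v2 if u2 == n else u2
    p1 = _orient_path(np.asarray(d1["path"]), o1)
    p2 = _orient_path(np.asarray(d2["path"]), n)
    g.remove_edge(u1, v1, k1)
    g.remove_edge(u2, v2, k2)
    g.remove_node(n)
    w1, w2 = len(p1), len(p2)
    g.add_edge(o1, o2, path=np.concatenate([p1, p2[1:]]),
               length_nm=d1["length_nm"] + d2["length_nm"],
               mean_height_nm=(d1["mean_height_nm"] * w1 + d2["mean_height_nm"] * w2)
               / (w1 + w2))


def _find_antibody(anat: Anatomy, topo: Topograph, mask: np.ndarray,
                   height_min_nm: float, min_blob_px: int = 3):
    """Locate an antibody blob and return its (begin, center, end) fractions
    along the backbone from the N end, or None."""
    tall = mask & (topo.heights >= height_min_nm)
    lab, n_blobs = ndimage.label(tall, structure=np.ones((3, 3), dtype=int))
    if n_blobs == 0:
        return None
    sizes = ndimage.sum_labels(tall, lab, index=range(1, n_blobs + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_blob_px:
        return None
    blob = np.argwhere(lab == best)

    # metric arc-length lookup along the backbone (N to C)
    pts, fracs = _backbone_param(anat)
    rels = []
    for pxl in blob:
        d2 = ((pts - pxl) ** 2).sum(axis=1)
        rels.append(fracs[int(np.argmin(d2))])
    rels = np.asarray(rels)
    lo, hi = float(rels.min()), float(rels.max())
    mid = float(np.clip(rels.mean(), lo, hi))
    return (lo, mid, hi)


def _backbone_param(anat: Anatomy):
    """Pixel coordinates along the backbone with their metric fraction of the
    total molecule length (arms averaged in at the N side)."""
    arm_n = sum(anat.n_end.arm_lengths_nm) / 2.0
    total = anat.total_length_for_positions()
    pts_all, frac_all = [], []
    offset = arm_n
    seen_bubble_once = False
    for kind, p, ln in anat.backbone_path:
        start = offset
        if kind == "bubble" and seen_bubble_once:
            start = bubble_start    # second strand shares the span
        n = len(p)
        t = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
        pts_all.append(p)
        frac_all.append((start + t * ln) / total)
        if kind == "bubble":
            if not seen_bubble_once:
                bubble_start = start
                offset = start + ln
                seen_bubble_once = True
        else:
            offset = start + ln
    return np.concatenate(pts_all), np.concatenate(frac_all)


def _total_length(anat: Anatomy) -> float:
    arm_n = sum(anat.n_end.arm_lengths_nm) / 2.0
    arm_c = sum(anat.c_end.arm_lengths_nm) / 2.0
    bub = sum(anat.bubble_strands_nm) / 2.0
    return arm_n + anat.stalk_n_nm + bub + anat.stalk_c_nm + arm_c


Anatomy.total_length_for_positions = _total_length


def measure_segments(anat: Anatomy) -> SegmentLengths:
    """Read the X1..X8 segment lengths off an annotated anatomy."""
    n1, n2 = anat.n_end.arm_lengths_nm if anat.n_end.splayed else (0.0, 0.0)
    c1, c2 = anat.c_end.arm_lengths_nm if anat.c_end.splayed else (0.0, 0.0)
    x4, x5 = anat.bubble_strands_nm
    return SegmentLengths(x1=n1, x2=n2, x3=anat.stalk_n_nm, x4=x4, x5=x5,
                          x6=anat.stalk_c_nm, x7=c1, x8=c2)
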