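"""Synthetic AFM topographs of dimeric coiled-coil molecules with ground truth.

This module generates seeded populations of surface-adsorbed, worm-like-chain
molecules rendered as AFM height maps, emulating air scans of a long golgin
tether deposited on mica: 1.2 um x 1.2 um fields at 512x512 px, a duplex
ridge of ~1.5 nm height within a ~2.5 nm Z range, terminal globules (an
N-terminal GFP cap, a smaller C-terminal GRIP-domain cap), optional antibody
label, stochastic end splaying, and a central unwinding "bubble" rendered as
two laterally bowed strands.  Images carry the usual scan nuisances: plane
slant, per-scan-line offsets, tip broadening (grayscale dilation by a
spherical tip of 2-5 nm radius) and Gaussian height noise.

Every generated molecule comes with a :class:`GroundTruthRecord` so that
detection, tracing and measurement can be validated without any real scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .topograph import Topograph
from .conformations import conformation_label


class InvalidParameterError(ValueError):
    pass


class PlacementError(ValueError):
    pass


# --------------------------------------------------------------------------
# specifications


@dataclass
class ScanSpec:
    """Geometry and nuisance parameters of a simulated raster scan."""

    field_size_nm: float = 1200.0
    resolution_px: int = 512
    tip_radius_nm: float = 3.0
    backbone_height_nm: float = 1.5
    globule_height_nm_gfp: float = 2.5
    globule_height_nm_grip: float = 2.0
    antibody_height_nm: float = 4.0
    noise_sd_nm: float = 0.15
    slant_row_sd_nm: float = 0.3
    slant_plane_gradient_nm_per_px: float = 0.004
    z_range_nm: float = 2.5

    def __post_init__(self) -> None:
        if self.resolution_px < 64:
            raise InvalidParameterError(f"resolution_px must be >= 64, got {self.resolution_px}")
        if not (self.field_size_nm > 0 and math.isfinite(self.field_size_nm)):
            raise InvalidParameterError(f"field_size_nm must be positive, got {self.field_size_nm}")
        if self.tip_radius_nm < 0:
            raise InvalidParameterError("tip_radius_nm must be >= 0")
        if self.noise_sd_nm < 0:
            raise InvalidParameterError("noise_sd_nm must be >= 0")
        for name in ("backbone_height_nm", "globule_height_nm_gfp",
                     "globule_height_nm_grip", "antibody_height_nm"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (self.pixel_size_nm > 0 and math.isfinite(self.pixel_size_nm)):
            raise InvalidParameterError("pixel size must be finite and positive")

    @property
    def pixel_size_nm(self) -> float:
        return self.field_size_nm / self.resolution_px


@dataclass
class MoleculePopulationSpec:
    """Stochastic model of one population (condition / construct) of molecules.

    Probabilities are per draw; lengths are in nm.  ``splay_prob_per_end``
    is the independent probability that each terminus of the dimer is
    splayed into two visible arms; ``bubble_prob`` the probability of a
    central unwinding bubble whose two strands have Gaussian lengths.
    """

    n_molecules: int = 200
    contour_length_mean_nm: float = 145.0
    contour_length_sd_nm: float = 15.0
    persistence_length_nm: float = 50.0
    splay_prob_per_end: float = 0.6164
    splay_arm_length_mean_nm: float = 20.0
    splay_arm_length_sd_nm: float = 5.0
    bubble_prob: float = 0.5
    bubble_strand_length_mean_nm: float = 27.0
    bubble_strand_length_sd_nm: float = 7.0
    bubble_strand_asym_sd_nm: float = 3.0
    bubble_center_rel: float = 0.48
    bubble_lateral_offset_nm: float = 8.0
    has_gfp: bool = True
    has_grip: bool = True
    antibody_label_rel: float | None = None
    molecules_per_field: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("splay_prob_per_end", "bubble_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {p}")
        if self.antibody_label_rel is not None and not 0.0 <= self.antibody_label_rel <= 1.0:
            raise InvalidParameterError("antibody_label_rel must be in [0, 1]")
        if not 0.0 < self.bubble_center_rel < 1.0:
            raise InvalidParameterError("bubble_center_rel must be in (0, 1)")
        for name in ("contour_length_mean_nm", "contour_length_sd_nm",
                     "persistence_length_nm", "splay_arm_length_mean_nm",
                     "splay_arm_length_sd_nm", "bubble_strand_length_mean_nm",
                     "bubble_strand_length_sd_nm", "bubble_lateral_offset_nm"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_molecules < 0 or self.molecules_per_field < 1:
            raise InvalidParameterError("bad molecule counts")


@dataclass
class GroundTruthRecord:
    """Per-molecule generative truth, the twin of a manual annotation."""

    molecule_id: int
    true_contour_length_nm: float
    n_splayed_ends: int
    splay_arm_lengths_nm: tuple[float, ...]      # up to 4: N1, N2, C1, C2
    has_bubble: bool
    bubble_strand_lengths_nm: tuple[float, float]
    bubble_span_rel: tuple[float, float]
    label_rel: float | None
    class_label: str
    n_splayed: bool = False
    c_splayed: bool = False
    placement: tuple[float, float, float] = (0.0, 0.0, 0.0)  # x_nm, y_nm, angle_rad
    field_index: int = 0
    touches_border: bool = False
    overlaps_other: bool = False

    def __post_init__(self) -> None:
        if self.true_contour_length_nm <= 0:
            raise InvalidParameterError("true_contour_length_nm must be > 0")
        if self.has_bubble:
            a, b = self.bubble_span_rel
            if not (0.0 <= a < b <= 1.0):
                raise InvalidParameterError(f"bad bubble_span_rel {self.bubble_span_rel}")
        expected = conformation_label(self.n_splayed, self.c_splayed, self.has_bubble)
        if self.class_label != expected:
            raise InvalidParameterError(
                f"class_label {self.class_label!r} inconsistent with flags ({expected!r})")


# --------------------------------------------------------------------------
# backbone model


def sample_backbone(contour_length_nm: float, persistence_length_nm: float,
                    step_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a planar worm-like chain as an ordered polyline (nm).

    Discrete 2D WLC: successive turning angles are i.i.d. zero-mean Gaussian
    with variance ``step_nm / persistence_length_nm``, giving a tangent
    correlation that decays as exp(-s / (2 Lp)), the planar convention for a
    persistence length Lp.  The chain starts at the origin with a uniformly
    random initial direction.

    Returns an ``(n+1, 2)`` array whose total polyline length equals
    ``contour_length_nm`` to within one step.
    """
    if contour_length_nm <= 0 or persistence_length_nm <= 0 or step_nm <= 0:
        raise InvalidParameterError("lengths must be positive")
    if step_nm > contour_length_nm / 10:
        raise InvalidParameterError(
            f"step_nm={step_nm} too coarse for contour {contour_length_nm} (need <= L/10)")
    n = max(10, int(round(contour_length_nm / step_nm)))
    step = contour_length_nm / n
    turn_sd = math.sqrt(step / persistence_length_nm)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.normal(0.0, turn_sd, size=n - 1)
    theta = theta0 + np.concatenate(([0.0], np.cumsum(turns)))
    steps = step * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])


def wlc_mean_square_end_to_end(contour_length_nm: float,
                               persistence_length_nm: float) -> float:
    """Closed-form <R^2> of the planar worm-like chain used by the sampler.

    With tangent correlation exp(-s/lam), lam = 2 Lp:
    <R^2> = 2 lam L - 2 lam^2 (1 - exp(-L/lam)).
    """
    lam = 2.0 * persistence_length_nm
    L = contour_length_nm
    return 2.0 * lam * L - 2.0 * lam * lam * (1.0 - math.exp(-L / lam))


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arclength(points: np.ndarray, s_cum: np.ndarray, s: float) -> np.ndarray:
    s = float(np.clip(s, 0.0, s_cum[-1]))
    i = int(np.searchsorted(s_cum, s, side="right")) - 1
    i = min(max(i, 0), len(points) - 2)
    ds = s_cum[i + 1] - s_cum[i]
    t = 0.0 if ds == 0 else (s - s_cum[i]) / ds
    return points[i] * (1 - t) + points[i + 1] * t


def _chord_for_separation(s1: float, s2: float, separation: float) -> float:
    """Chord length such that two arcs of lengths s1, s2 bulging to opposite
    sides of the chord are ``separation`` apart at their midpoints.

    Falls back to the geometric limits (half / just under the shorter
    strand) when the requested separation is unreachable.
    """
    s_min = min(s1, s2)

    def bulge(arc: float, chord: float) -> float:
        ratio = min(chord / arc, 1.0 - 1e-9)
        a = brentq(lambda x: math.sin(x) / x - ratio, 1e-9, math.pi - 1e-9)
        R = arc / (2.0 * a)
        return R * (1.0 - math.cos(a))

    def f(chord: float) -> float:
        return bulge(s1, chord) + bulge(s2, chord) - separation

    lo, hi = 0.5 * s_min, 0.995 * s_min
    if f(hi) > 0:        # even the flattest lens is wider than asked
        return hi
    if f(lo) < 0:        # cannot open that wide without shrinking the chord
        return lo
    return brentq(f, lo, hi)


def _circular_arc(p0: np.ndarray, p1: np.ndarray, arc_length: float,
                  side: int, n_pts: int = 40) -> np.ndarray:
    """Circular arc from p0 to p1 with the given arc length, bulging to
    ``side`` (+1 left of the chord, -1 right).  Requires arc_length >= chord."""
    chord = float(np.linalg.norm(p1 - p0))
    if arc_length < chord:
        raise InvalidParameterError(
            f"arc length {arc_length:.3g} shorter than chord {chord:.3g}")
    if chord == 0:
        raise InvalidParameterError("degenerate arc: coincident endpoints")
    ratio = chord / arc_length
    if ratio > 1.0 - 1e-9:           # essentially straight
        t = np.linspace(0.0, 1.0, n_pts)[:, None]
        return p0 * (1 - t) + p1 * t
    # solve sin(a)/a = chord/arc for half-angle a in (0, pi)
    f = lambda a: math.sin(a) / a - ratio
    a = brentq(f, 1e-9, math.pi - 1e-9)
    R = arc_length / (2.0 * a)
    mid = 0.5 * (p0 + p1)
    u = (p1 - p0) / chord
    nvec = side * np.array([-u[1], u[0]])
    h = R * math.cos(a)
    center = mid - nvec * h
    ang0 = math.atan2(*(p0 - center)[::-1])
    ang1 = math.atan2(*(p1 - center)[::-1])
    # two sweeps join ang0 to ang1; the bulge arc is the one subtending 2a
    s_pos = (ang1 - ang0) % (2 * math.pi)
    s_neg = s_pos - 2 * math.pi
    sweep = s_pos if abs(abs(s_pos) - 2 * a) <= abs(abs(s_neg) - 2 * a) else s_neg
    angs = ang0 + np.linspace(0.0, sweep, n_pts)
    return center + R * np.column_stack([np.cos(angs), np.sin(angs)])


# --------------------------------------------------------------------------
# per-molecule feature construction


@dataclass
class MoleculeDraw:
    """One molecule's random draw from a :class:`MoleculePopulationSpec`."""

    contour_length_nm: float
    n_splayed: bool
    c_splayed: bool
    arm_lengths_nm: tuple[float, float, float, float]  # N1 N2 C1 C2 (0 if unused)
    has_bubble: bool
    bubble_strand_lengths_nm: tuple[float, float]
    bubble_center_rel: float
    label_rel: float | None
    has_gfp: bool
    has_grip: bool
    bubble_lateral_offset_nm: float


def draw_molecule(spec: MoleculePopulationSpec, rng: np.random.Generator) -> MoleculeDraw:
    L = max(30.0, rng.normal(spec.contour_length_mean_nm, spec.contour_length_sd_nm))
    n_spl = bool(rng.random() < spec.splay_prob_per_end)
    c_spl = bool(rng.random() < spec.splay_prob_per_end)

    def arm() -> float:
        return float(np.clip(rng.normal(spec.splay_arm_length_mean_nm,
                                        spec.splay_arm_length_sd_nm), 8.0, L / 3))

    arms = (arm() if n_spl else 0.0, arm() if n_spl else 0.0,
            arm() if c_spl else 0.0, arm() if c_spl else 0.0)
    bub = bool(rng.random() < spec.bubble_prob)
    if bub:
        m = max(10.0, rng.normal(spec.bubble_strand_length_mean_nm,
                                 spec.bubble_strand_length_sd_nm))
        d = abs(rng.normal(0.0, spec.bubble_strand_asym_sd_nm))
        strands = (m + 0.5 * d, max(8.0, m - 0.5 * d))
        # a short molecule cannot unwind over more than its stalk
        n_trim = (arms[0] + arms[1]) / 2
        c_trim = (arms[2] + arms[3]) / 2
        if sum(strands) / 2 >= L - n_trim - c_trim - 12.0:
            bub, strands = False, (0.0, 0.0)
    else:
        strands = (0.0, 0.0)
    return MoleculeDraw(
        contour_length_nm=L, n_splayed=n_spl, c_splayed=c_spl,
        arm_lengths_nm=arms, has_bubble=bub, bubble_strand_lengths_nm=strands,
        bubble_center_rel=spec.bubble_center_rel, label_rel=spec.antibody_label_rel,
        has_gfp=spec.has_gfp, has_grip=spec.has_grip,
        bubble_lateral_offset_nm=spec.bubble_lateral_offset_nm)


@dataclass
class MoleculeGeometry:
    """Renderable geometry of one molecule in molecule-local nm coordinates."""

    polylines: list[tuple[np.ndarray, str]] = field(default_factory=list)
    # disks: (center_xy_nm, radius_nm, height_nm, kind)
    disks: list[tuple[np.ndarray, float, float, str]] = field(default_factory=list)
    truth: GroundTruthRecord | None = None

    def all_points(self) -> np.ndarray:
        pts = [p for p, _ in self.polylines] + [c[None, :] for c, *_ in self.disks]
        return np.concatenate(pts, axis=0)


GFP_RADIUS_NM = 3.5
GRIP_RADIUS_NM = 3.0
ANTIBODY_RADIUS_NM = 5.0
ANTIBODY_OFFSET_NM = 6.0
_ARM_BASE_ANGLE = math.radians(28.0)


def _tangent(points: np.ndarray, idx_from: int, idx_to: int) -> np.ndarray:
    v = points[idx_to] - points[idx_from]
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def add_features(backbone: np.ndarray, draw: MoleculeDraw,
                 rng: np.random.Generator,
                 molecule_id: int = 0) -> MoleculeGeometry:
    """Decorate a backbone polyline with the anatomy of one dimer.

    At each splayed end the terminal sub-path of arc length equal to the
    mean of the two arm lengths is replaced by two diverging arm polylines
    rooted at the splay junction, so the length a tracer measures —
    averaging paired arms — matches the drawn contour.  A bubble likewise
    replaces a central sub-path by two laterally bowed circular-arc strands
    sharing its endpoints.  Terminal globules (GFP, GRIP) and an optional
    antibody blob are added as spherical-cap disks.

    Returns the geometry together with its :class:`GroundTruthRecord`;
    ``true_contour_length_nm`` is the arc length an ideal tracer would
    report (remaining duplex + averaged arms + averaged strands).
    """
    if len(backbone) < 2:
        raise InvalidParameterError("backbone must have at least 2 points")
    s_cum = _polyline_arclength(backbone)
    L = float(s_cum[-1])

    n_trim = (draw.arm_lengths_nm[0] + draw.arm_lengths_nm[1]) / 2 if draw.n_splayed else 0.0
    c_trim = (draw.arm_lengths_nm[2] + draw.arm_lengths_nm[3]) / 2 if draw.c_splayed else 0.0
    span = 0.0
    if draw.has_bubble:
        s1, s2 = draw.bubble_strand_lengths_nm
        span = _chord_for_separation(s1, s2, draw.bubble_lateral_offset_nm)
        if span >= L - n_trim - c_trim - 10.0:
            raise InvalidParameterError("bubble span longer than available backbone")
    lo_keep, hi_keep = n_trim, L - c_trim
    if lo_keep >= hi_keep:
        raise InvalidParameterError("splay arms consume the whole backbone")

    geom = MoleculeGeometry()
    dense_s = np.linspace(lo_keep, hi_keep, max(2, int((hi_keep - lo_keep) / 1.0) + 1))
    stalk = np.array([_point_at_arclength(backbone, s_cum, s) for s in dense_s])
    stalk_cum = _polyline_arclength(stalk)

    bubble_span_rel = (0.0, 0.0)
    eff_len = (hi_keep - lo_keep) + n_trim + c_trim  # averaged arms == trims
    if draw.has_bubble:
        s1, s2 = draw.bubble_strand_lengths_nm
        center_s = lo_keep + draw.bubble_center_rel * (hi_keep - lo_keep)
        a_s = max(lo_keep + 5.0, center_s - span / 2)
        b_s = min(hi_keep - 5.0, a_s + span)
        a_s = b_s - span
        pa = _point_at_arclength(backbone, s_cum, a_s)
        pb = _point_at_arclength(backbone, s_cum, b_s)
        chord = float(np.linalg.norm(pb - pa))
        # chord <= span <= 0.995 * shorter strand by construction; the
        # render-side floor below never alters the recorded ground truth
        arc1 = _circular_arc(pa, pb, max(s1, chord * 1.001), side=+1)
        arc2 = _circular_arc(pa, pb, max(s2, chord * 1.001), side=-1)
        pre_mask = dense_s <= a_s
        post_mask = dense_s >= b_s
        pre = np.array([_point_at_arclength(backbone, s_cum, s)
                        for s in dense_s[pre_mask]] + [pa])
        post = np.concatenate([[pb], np.array(
            [_point_at_arclength(backbone, s_cum, s) for s in dense_s[post_mask]])])
        geom.polylines.append((pre, "stalk_n"))
        geom.polylines.append((arc1, "bubble_strand"))
        geom.polylines.append((arc2, "bubble_strand"))
        geom.polylines.append((post, "stalk_c"))
        removed = b_s - a_s
        eff_len = eff_len - removed + (s1 + s2) / 2.0
        bubble_span_rel = ((a_s - lo_keep + n_trim) / eff_len,
                           (a_s - lo_keep + n_trim + (s1 + s2) / 2.0) / eff_len)
        draw.bubble_strand_lengths_nm = (s1, s2)
        n_terminus, c_terminus = pre[0], post[-1]
        n_tan = _tangent(pre, min(5, len(pre) - 1), 0)
        c_tan = _tangent(post, max(len(post) - 6, 0), len(post) - 1)
    else:
        geom.polylines.append((stalk, "stalk"))
        n_terminus, c_terminus = stalk[0], stalk[-1]
        n_tan = _tangent(stalk, min(5, len(stalk) - 1), 0)
        c_tan = _tangent(stalk, max(len(stalk) - 6, 0), len(stalk) - 1)

    def make_arms(root: np.ndarray, tangent: np.ndarray,
                  lengths: tuple[float, float], kind: str) -> list[np.ndarray]:
        tips = []
        for a_len, sign in zip(lengths, (+1, -1)):
            phi = sign * (_ARM_BASE_ANGLE + rng.uniform(-0.15, 0.25))
            c, s = math.cos(phi), math.sin(phi)
            d = np.array([c * tangent[0] - s * tangent[1],
                          s * tangent[0] + c * tangent[1]])
            n_pts = max(2, int(a_len / 1.0))
            t = np.linspace(0.0, a_len, n_pts)[:, None]
            # slight outward curvature so arms separate visibly
            bend = sign * np.linspace(0.0, 0.25, n_pts)
            db = np.column_stack([np.cos(bend) * d[0] - np.sin(bend) * d[1],
                                  np.sin(bend) * d[0] + np.cos(bend) * d[1]])
            pts = root + np.cumsum(np.vstack([[0, 0], np.diff(t, axis=0) * db[1:]]), axis=0)
            geom.polylines.append((pts, kind))
            tips.append(pts[-1])
        return tips

    if draw.n_splayed:
        n_tips = make_arms(n_terminus, n_tan, draw.arm_lengths_nm[:2], "arm_n")
    else:
        n_tips = [n_terminus]
    if draw.c_splayed:
        c_tips = make_arms(c_terminus, c_tan, draw.arm_lengths_nm[2:], "arm_c")
    else:
        c_tips = [c_terminus]

    if draw.has_gfp:
        for tip in n_tips:
            geom.disks.append((np.asarray(tip, float), GFP_RADIUS_NM, -1.0, "gfp"))
    if draw.has_grip:
        for tip in c_tips:
            geom.disks.append((np.asarray(tip, float), GRIP_RADIUS_NM, -1.0, "grip"))

    if draw.label_rel is not None:
        # label position measured from the N terminus along the effective path
        s_lab = lo_keep + draw.label_rel * (hi_keep - lo_keep)
        p_lab = _point_at_arclength(backbone, s_cum, s_lab)
        tan = _tangent(backbone,
                       max(0, int(np.searchsorted(s_cum, s_lab)) - 2),
                       min(len(backbone) - 1, int(np.searchsorted(s_cum, s_lab)) + 2))
        nvec = np.array([-tan[1], tan[0]])
        center = p_lab + nvec * ANTIBODY_OFFSET_NM * (1 if rng.random() < 0.5 else -1)
        geom.disks.append((center, ANTIBODY_RADIUS_NM, -2.0, "antibody"))

    n_ends = int(draw.n_splayed) + int(draw.c_splayed)
    truth = GroundTruthRecord(
        molecule_id=molecule_id,
        true_contour_length_nm=eff_len,
        n_splayed_ends=n_ends,
        splay_arm_lengths_nm=draw.arm_lengths_nm,
        has_bubble=draw.has_bubble,
        bubble_strand_lengths_nm=draw.bubble_strand_lengths_nm,
        bubble_span_rel=bubble_span_rel if draw.has_bubble else (0.0, 0.0),
        label_rel=draw.label_rel,
        class_label=conformation_label(draw.n_splayed, draw.c_splayed, draw.has_bubble),
        n_splayed=draw.n_splayed, c_splayed=draw.c_splayed)
    geom.truth = truth
    return geom


# --------------------------------------------------------------------------
# rendering

RIDGE_RADIUS_NM = 1.0


def tip_structure(tip_radius_nm: float, pixel_size_nm: float) -> np.ndarray | None:
    """Spherical-tip structuring element for grayscale dilation.

    Element value at lateral offset d is -(R - sqrt(R^2 - d^2)): the image of
    a surface under a tip of radius R is the max over the footprint of
    (surface height + element), which preserves the apex height of isolated
    convex features while broadening them laterally.
    Returns None when the footprint does not extend beyond the centre pixel.
    """
    if tip_radius_nm <= 0:
        return None
    r_px = int(math.floor(tip_radius_nm / pixel_size_nm))
    if r_px < 1:
        return None
    yy, xx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
    d = np.hypot(yy, xx) * pixel_size_nm
    elem = -(tip_radius_nm - np.sqrt(np.maximum(tip_radius_nm ** 2 - d ** 2, 0.0)))
    # offsets outside the tip footprint can never win the max: large negative
    elem[d > tip_radius_nm] = -1.0e12
    return elem


def apply_tip(surface: np.ndarray, tip_radius_nm: float, pixel_size_nm: float) -> np.ndarray:
    """Grayscale dilation of a height map by a spherical tip."""
    elem = tip_structure(tip_radius_nm, pixel_size_nm)
    if elem is None:
        return surface.copy()
    out = ndimage.grey_dilation(surface, structure=elem, mode="constant", cval=0.0)
    return np.maximum(out, surface)


def _stamp_polyline(H: np.ndarray, points_nm: np.ndarray, height: float,
                    radius_nm: float, px: float) -> None:
    """Max-stamp a ridge of given height along a polyline (flat-top profile)."""
    seg = np.linalg.norm(np.diff(points_nm, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return
    n = max(2, int(total / (0.3 * px)) + 1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, total, n)
    xs = np.interp(s, s_cum, points_nm[:, 0])
    ys = np.interp(s, s_cum, points_nm[:, 1])
    r_px = max(radius_nm / px, 0.55)
    ir = int(math.ceil(r_px))
    rows, cols = H.shape
    for x, y in zip(xs / px, ys / px):
        ci, ri = int(round(x)), int(round(y))
        for dy in range(-ir, ir + 1):
            for dx in range(-ir, ir + 1):
                if dx * dx + dy * dy <= r_px * r_px:
                    r, c = ri + dy, ci + dx
                    if 0 <= r < rows and 0 <= c < cols:
                        if H[r, c] < height:
                            H[r, c] = height


def _stamp_disk(H: np.ndarray, center_nm: np.ndarray, radius_nm: float,
                height: float, px: float) -> None:
    """Max-stamp a spherical cap of apex ``height`` and lateral ``radius``."""
    rows, cols = H.shape
    cx, cy = center_nm / px
    ir = int(math.ceil(radius_nm / px)) + 1
    ci, ri = int(round(cx)), int(round(cy))
    for dy in range(-ir, ir + 1):
        for dx in range(-ir, ir + 1):
            r, c = ri + dy, ci + dx
            if not (0 <= r < rows and 0 <= c < cols):
                continue
            d = math.hypot((c - cx) * px, (r - cy) * px)
            if d <= radius_nm:
                h = height * math.sqrt(max(0.0, 1.0 - (d / radius_nm) ** 2))
                if H[r, c] < h:
                    H[r, c] = h


def rasterize_ideal(geometries: Sequence[MoleculeGeometry], spec: ScanSpec,
                    return_masks: bool = False):
    """Rasterize placed molecule geometries into an ideal (tip-free,
    noise-free, slant-free) height map.  Polylines become flat-top ridges of
    ``backbone_height_nm``; disks become spherical caps.  Heights combine by
    maximum."""
    px = spec.pixel_size_nm
    n = spec.resolution_px
    H = np.zeros((n, n))
    masks = []
    disk_heights = {"gfp": spec.globule_height_nm_gfp,
                    "grip": spec.globule_height_nm_grip,
                    "antibody": spec.antibody_height_nm}
    for geom in geometries:
        Hm = np.zeros_like(H) if return_masks else H
        target = Hm if return_masks else H
        for pts, _kind in geom.polylines:
            _stamp_polyline(target, pts, spec.backbone_height_nm, RIDGE_RADIUS_NM, px)
        for center, radius, h, kind in geom.disks:
            height = disk_heights.get(kind, h if h > 0 else spec.backbone_height_nm)
            _stamp_disk(target, center, radius, height, px)
        if return_masks:
            masks.append(target > 0)
            np.maximum(H, target, out=H)
    if return_masks:
        return H, masks
    return H


def place_geometries(geometries: Sequence[MoleculeGeometry], spec: ScanSpec,
                     rng: np.random.Generator,
                     max_overlap_frac: float = 0.6,
                     max_tries: int = 80) -> list[MoleculeGeometry]:
    """Place molecule geometries into the field: uniform random anchor and
    orientation, rejecting placements whose bounding-box overlap with any
    already-placed molecule exceeds ``max_overlap_frac`` of the smaller box.
    Border contact is recorded in the ground truth, not prevented."""
    placed: list[MoleculeGeometry] = []
    boxes: list[tuple[float, float, float, float]] = []
    F = spec.field_size_nm
    for geom in geometries:
        pts = geom.all_points()
        ext = pts.max(axis=0) - pts.min(axis=0)
        if max(ext) > 2 * F:
            raise PlacementError(f"geometry extent {max(ext):.0f} nm exceeds 2x field size")
        chosen = None
        for _ in range(max_tries):
            ang = rng.uniform(0, 2 * math.pi)
            R = np.array([[math.cos(ang), -math.sin(ang)],
                          [math.sin(ang), math.cos(ang)]])
            anchor = rng.uniform(0.05 * F, 0.95 * F, size=2)
            c = pts.mean(axis=0)
            moved = (pts - c) @ R.T + anchor
            lo, hi = moved.min(axis=0), moved.max(axis=0)
            box = (lo[0], lo[1], hi[0], hi[1])
            ov = _max_box_overlap(box, boxes)
            if ov <= max_overlap_frac:
                chosen = (R, c, anchor, box, ov)
                break
        if chosen is None:
            chosen = (R, c, anchor, box, ov)  # accept last try, flagged as overlap
        R, c, anchor, box, ov = chosen
        new = MoleculeGeometry(truth=geom.truth)
        for p, kind in geom.polylines:
            new.polylines.append(((p - c) @ R.T + anchor, kind))
        for center, radius, h, kind in geom.disks:
            new.disks.append((((center - c) @ R.T + anchor), radius, h, kind))
        npts = new.all_points()
        margin = 2.0  # nm: ridge/cap radius reaches beyond the centreline
        touches = bool((npts - margin < 0).any() or (npts + margin > F).any())
        tr = new.truth
        new.truth = replace(tr, placement=(float(anchor[0]), float(anchor[1]), float(ang)),
                            touches_border=touches, overlaps_other=bool(ov > 0.0))
        placed.append(new)
        boxes.append(box)
    return placed


def _max_box_overlap(box, boxes) -> float:
    best = 0.0
    ax0, ay0, ax1, ay1 = box
    a_area = max(ax1 - ax0, 1e-9) * max(ay1 - ay0, 1e-9)
    for bx0, by0, bx1, by1 in boxes:
        w = min(ax1, bx1) - max(ax0, bx0)
        h = min(ay1, by1) - max(ay0, by0)
        if w > 0 and h > 0:
            b_area = max(bx1 - bx0, 1e-9) * max(by1 - by0, 1e-9)
            best = max(best, w * h / min(a_area, b_area))
    return best


def render_topograph(geometries: Sequence[MoleculeGeometry], spec: ScanSpec,
                     rng: np.random.Generator,
                     return_masks: bool = False):
    """Render placed geometries to a raw topograph: rasterize, dilate by the
    tip, add plane slant, per-row offsets and Gaussian noise.

    Returns ``(Topograph, [GroundTruthRecord])`` (plus per-molecule footprint
    masks when ``return_masks``).  The returned topograph has provenance
    "raw": it still carries slant and must be flattened before analysis.
    """
    if return_masks:
        ideal, masks = rasterize_ideal(geometries, spec, return_masks=True)
    else:
        ideal = rasterize_ideal(geometries, spec)
    H = apply_tip(ideal, spec.tip_radius_nm, spec.pixel_size_nm)
    n = spec.resolution_px
    if spec.slant_plane_gradient_nm_per_px > 0:
        ang = rng.uniform(0, 2 * math.pi)
        rr, cc = np.mgrid[0:n, 0:n]
        H = H + spec.slant_plane_gradient_nm_per_px * (math.cos(ang) * cc + math.sin(ang) * rr)
    if spec.slant_row_sd_nm > 0:
        H = H + rng.normal(0.0, spec.slant_row_sd_nm, size=(n, 1))
    if spec.noise_sd_nm > 0:
        H = H + rng.normal(0.0, spec.noise_sd_nm, size=H.shape)
    topo = Topograph(H, spec.pixel_size_nm, provenance="raw",
                     metadata={"tip_radius_nm": spec.tip_radius_nm})
    truths = [g.truth for g in geometries]
    if return_masks:
        return topo, truths, masks
    return topo, truths


# --------------------------------------------------------------------------
# population generation


def generate_population(pop: MoleculePopulationSpec, scan: ScanSpec,
                        return_masks: bool = False):
    """Generate a full population: a list of (Topograph, [GroundTruthRecord])
    field pairs, deterministic for a fixed ``pop.seed``.

    Each molecule uses its own child random stream of the root seed, so the
    population's ground truth does not depend on how molecules are batched
    into fields.
    """
    root = np.random.SeedSequence(pop.seed)
    n_fields = max(1, math.ceil(pop.n_molecules / pop.molecules_per_field)) \
        if pop.n_molecules else 1
    mol_ss = root.spawn(pop.n_molecules + n_fields)
    fields = []
    mol_idx = 0
    for fi in range(n_fields):
        geoms = []
        n_here = min(pop.molecules_per_field, pop.n_molecules - mol_idx)
        for _ in range(max(0, n_here)):
            rng = np.random.default_rng(mol_ss[mol_idx])
            d = draw_molecule(pop, rng)
            bb = sample_backbone(d.contour_length_nm, pop.persistence_length_nm,
                                 step_nm=min(scan.pixel_size_nm, d.contour_length_nm / 20),
                                 rng=rng)
            g = add_features(bb, d, rng, molecule_id=mol_idx)
            g.truth = replace(g.truth, field_index=fi)
            geoms.append(g)
            mol_idx += 1
        field_rng = np.random.default_rng(mol_ss[pop.n_molecules + fi])
        placed = place_geometries(geoms, scan, field_rng)
        placed = [replace_field(g, fi) for g in placed]
        out = render_topograph(placed, scan, field_rng, return_masks=return_masks)
        fields.append(out)
    return fields


def replace_field(geom: MoleculeGeometry, fi: int) -> MoleculeGeometry:
    geom.truth = replace(geom.truth, field_index=fi)
    return geom


# --------------------------------------------------------------------------
# presets: the study conditions

#: Wild-type full-length tether: ~145 nm contour, splay probability per end
#: calibrated so that 38% of dimers splay at both ends (and hence ~85% at
#: one or more), half of molecules carrying a central bubble of ~27 nm.
PRESET_WT = MoleculePopulationSpec()

#: Hinge-deletion mutant: stiffer, rarer (20%) and smaller (~17 nm, tighter
#: spread) bubbles; 105 residues shorter than wild type.
PRESET_DHINGE = replace(
    PRESET_WT, contour_length_mean_nm=134.0, contour_length_sd_nm=12.0,
    persistence_length_nm=150.0, bubble_prob=0.2,
    bubble_strand_length_mean_nm=17.0, bubble_strand_length_sd_nm=2.5,
    bubble_strand_asym_sd_nm=1.5)

#: Non-reducing purification: rod-like molecules, few splays or bubbles.
PRESET_NODTT = replace(
    PRESET_WT, splay_prob_per_end=0.08, bubble_prob=0.04,
    persistence_length_nm=1.0e4)

#: Antibody-labelled wild type (epitope tag in the central hinge region).
PRESET_WT_LABELED = replace(PRESET_WT, antibody_label_rel=0.48)

# N- and C-terminal halves / quarters of the protein. The N-terminal half is
# the construct with a printed measured mean (91.2 nm); the C-half mean is
# set so the halves sum to the full-length mean. Quarter fragments use the
# same ~30% compaction relative to the canonical coiled-coil rise.
_FRAGMENTS = {
    "1-358": (358, 37.0),
    "394-751": (358, 37.0),
    "1-889": (889, 91.2),
    "890-1684": (795, 53.8),
}


def fragment_preset(name: str) -> MoleculePopulationSpec:
    if name not in _FRAGMENTS:
        raise InvalidParameterError(
            f"unknown fragment {name!r}; known: {sorted(_FRAGMENTS)}")
    residues, mean_nm = _FRAGMENTS[name]
    return replace(
        PRESET_WT, contour_length_mean_nm=mean_nm,
        contour_length_sd_nm=0.1 * mean_nm,
        bubble_prob=0.5 if name in ("1-889",) else 0.0,
        bubble_strand_length_mean_nm=min(27.0, 0.3 * mean_nm),
        splay_arm_length_mean_nm=min(20.0, 0.25 * mean_nm),
        has_grip=(name == "890-1684"))


def get_preset(name: str) -> MoleculePopulationSpec:
    """Look up a named population preset (wt, dhinge, noDTT, wt-ha,
    fragment:<range>)."""
    table = {"wt": PRESET_WT, "dhinge": PRESET_DHINGE, "noDTT": PRESET_NODTT,
             "wt-ha": PRESET_WT_LABELED}
    if name in table:
        return table[name]
    if name.startswith("fragment:"):
        return fragment_preset(name.split(":", 1)[1])
    raise InvalidParameterError(f"unknown preset {name!r}")
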