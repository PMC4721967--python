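"""Per-molecule metrics and population statistics for tether morphometry.

The per-molecule quantities all derive from the X1..X8 segment decomposition
and the annotated anatomy:

* bubble size = (X4 + X5) / 2 — the mean of the two strand lengths;
* total length = (X1+X2)/2 + X3 + (X4+X5)/2 + X6 + (X7+X8)/2 — paired
  arms and strands are averaged, mirroring the bubble-size convention;
* normalized splay-to-splay distance = Euclidean distance between the two
  splay junctions divided by the traced backbone path length between them
  (chord over arc): ~1 for rigid, elongated molecules, small for bent or
  hairpinned ones.  For an unsplayed end the backbone terminus substitutes
  for the junction;
* relative feature positions = path length from the GFP (N) end to the
  beginning / center / end of the bubble or antibody label, as a fraction
  of total length;
* an 8-way conformational class from the three binary features.

Population-level helpers compute splay fractions with binomial confidence
intervals, the ends-independence consistency check, predicted coiled-coil
lengths from residue counts (rise 0.1485 nm/residue) and the percent
shortfall of measured vs predicted lengths, Welch two-sample comparisons,
and histogram / ECDF summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .anatomy import Anatomy, SegmentLengths
from .conformations import conformation_label


# --------------------------------------------------------------------------
# per-molecule metrics


def bubble_size(seg: SegmentLengths) -> float:
    """Mean of the two bubble strand lengths, (X4 + X5) / 2; 0 if no bubble."""
    return (seg.x4 + seg.x5) / 2.0


def total_length(seg: SegmentLengths) -> float:
    """(X1+X2)/2 + X3 + (X4+X5)/2 + X6 + (X7+X8)/2."""
    return ((seg.x1 + seg.x2) / 2.0 + seg.x3 + (seg.x4 + seg.x5) / 2.0
            + seg.x6 + (seg.x7 + seg.x8) / 2.0)


def normalized_splay_distance(anat: Anatomy) -> float | None:
    """Chord over arc between the two splay junctions (termini as fallback).

    Returns None for a degenerate path (coincident junctions).
    """
    arc = anat.backbone_length_nm()
    chord = anat.end_to_end_nm()
    if arc <= 0 or chord <= 0:
        return None
    return min(chord / arc, 1.0)


def relative_positions(anat: Anatomy, feature: str = "bubble",
                       ) -> tuple[float, float, float] | None:
    """(rel_begin, rel_center, rel_end) of a feature from the GFP end.

    Positions are path lengths from the N terminus (averaging paired arms
    and strands) divided by total length.  Withheld (None) when the
    molecule's orientation is ambiguous or the feature is absent.
    """
    if anat.orientation_ambiguous:
        return None
    if feature == "bubble":
        if not anat.has_bubble:
            return None
        total = anat.total_length_for_positions()
        begin = sum(anat.n_end.arm_lengths_nm) / 2.0 + anat.stalk_n_nm
        extent = sum(anat.bubble_strands_nm) / 2.0
        return (begin / total, (begin + extent / 2.0) / total,
                (begin + extent) / total)
    if feature == "antibody":
        return anat.antibody_rel
    raise ValueError(f"unknown feature {feature!r}")


def classify_conformation(anat: Anatomy) -> str:
    """One of the 8 classes from (N-splay, C-splay, bubble)."""
    return conformation_label(anat.n_end.splayed, anat.c_end.splayed,
                              anat.has_bubble)


@dataclass
class MoleculeMetrics:
    """Derived per-molecule quantities (one CSV row)."""

    molecule_id: int
    total_length_nm: float
    bubble_size_nm: float
    norm_splay_distance: float | None
    rel_begin: float | None
    rel_center: float | None
    rel_end: float | None
    conformation_class: str
    orientation_ambiguous: bool = False
    segments: SegmentLengths | None = None

    def __post_init__(self) -> None:
        _, _, has_bubble = _class_flags(self.conformation_class)
        if (self.bubble_size_nm > 0) != has_bubble:
            raise ValueError("bubble_size_nm inconsistent with conformation class")
        present = [p for p in (self.rel_begin, self.rel_center, self.rel_end)
                   if p is not None]
        if len(present) == 3 and not (self.rel_begin <= self.rel_center <= self.rel_end):
            raise ValueError("relative positions out of order")
        if self.norm_splay_distance is not None and not 0 < self.norm_splay_distance <= 1:
            raise ValueError("norm_splay_distance outside (0, 1]")


def _class_flags(label: str) -> tuple[bool, bool, bool]:
    from .conformations import class_features
    return class_features(label)


def molecule_metrics(anat: Anatomy, feature: str = "bubble") -> MoleculeMetrics:
    """Assemble the full metrics row for one annotated anatomy."""
    seg = _segments(anat)
    rel = relative_positions(anat, "antibody") if feature == "antibody" else \
        relative_positions(anat, "bubble")
    rb, rc, re_ = rel if rel is not None else (None, None, None)
    return MoleculeMetrics(
        molecule_id=anat.molecule_id,
        total_length_nm=total_length(seg),
        bubble_size_nm=bubble_size(seg),
        norm_splay_distance=normalized_splay_distance(anat),
        rel_begin=rb, rel_center=rc, rel_end=re_,
        conformation_class=classify_conformation(anat),
        orientation_ambiguous=anat.orientation_ambiguous,
        segments=seg)


def _segments(anat: Anatomy) -> SegmentLengths:
    from .anatomy import measure_segments
    return measure_segments(anat)


# --------------------------------------------------------------------------
# population statistics


@dataclass
class FractionWithCI:
    fraction: float
    n: int
    ci_low: float
    ci_high: float


def _binom_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    res = stats.binomtest(k, n).proportion_ci(confidence_level=conf, method="wilson")
    return (float(res.low), float(res.high))


def splay_fraction_stats(class_labels: list[str]) -> tuple[FractionWithCI, FractionWithCI]:
    """Empirical (fraction with >=1 splayed end, fraction with both ends
    splayed), each with a Wilson 95% binomial CI."""
    if not class_labels:
        raise ValueError("empty population")
    n = len(class_labels)
    flags = [_class_flags(c)[:2] for c in class_labels]
    k_any = sum(1 for a, b in flags if a or b)
    k_both = sum(1 for a, b in flags if a and b)
    return (FractionWithCI(k_any / n, n, *_binom_ci(k_any, n)),
            FractionWithCI(k_both / n, n, *_binom_ci(k_both, n)))


def independent_ends_check(frac_both: float) -> float:
    """Predicted fraction with >=1 splayed end if the two ends splay
    independently with equal probability p: p = sqrt(frac_both), prediction
    1 - (1 - p)^2.  A consistency check on the ends-independence model, not
    a measurement."""
    if not 0.0 <= frac_both <= 1.0:
        raise ValueError(f"frac_both must be in [0, 1], got {frac_both}")
    p = math.sqrt(frac_both)
    return 1.0 - (1.0 - p) ** 2


# --------------------------------------------------------------------------
# predicted lengths

#: Canonical axial rise of a coiled coil, nm per residue.
RISE_PER_RESIDUE_NM = 0.1485


@dataclass
class PredictionParams:
    """Residue counts and coiled-coil rise for predicted-length arithmetic."""

    rise_per_residue_nm: float = RISE_PER_RESIDUE_NM
    residue_counts: dict[str, int] = field(default_factory=lambda: {
        "full": 1684, "1-358": 358, "394-751": 358, "1-889": 889,
        "890-1684": 795})
    predicted_min_full_length_nm: float = 204.0

    def __post_init__(self) -> None:
        if self.rise_per_residue_nm <= 0:
            raise ValueError("rise_per_residue_nm must be > 0")
        if any(v <= 0 for v in self.residue_counts.values()):
            raise ValueError("residue counts must be positive")


def predicted_length(residue_count: int,
                     params: PredictionParams | None = None) -> float:
    """residue_count x rise_per_residue_nm, in nm."""
    params = params or PredictionParams()
    if residue_count <= 0:
        raise ValueError("residue_count must be positive")
    return residue_count * params.rise_per_residue_nm


def percent_shortfall(measured_mean_nm: float, predicted_nm: float) -> float:
    """100 x (1 - measured / predicted)."""
    if predicted_nm <= 0:
        raise ValueError("predicted length must be positive")
    return 100.0 * (1.0 - measured_mean_nm / predicted_nm)


# --------------------------------------------------------------------------
# group comparison and summaries


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float


def compare_groups(values_a, values_b) -> GroupComparison:
    """Welch (unequal-variance) unpaired two-tailed t test.

    Two groups with zero variance and equal means return p = 1 by
    convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, float(len(a) + len(b) - 2), 1.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass
class PopulationSummary:
    group: str
    n: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    ecdf_values: np.ndarray
    ecdf_fractions: np.ndarray


def summarize(values, group: str = "", bin_width: float = 10.0) -> PopulationSummary:
    """Mean, SD, fixed-bin-width histogram and ECDF of one group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty values")
    lo = math.floor(v.min() / bin_width) * bin_width
    hi = math.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    sv = np.sort(v)
    frac = np.arange(1, len(sv) + 1) / len(sv)
    return PopulationSummary(group, len(v), float(v.mean()),
                             float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                             edges, counts, sv, frac)


def ecdf_overlay(groups: dict[str, np.ndarray]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group (sorted values, cumulative fractions) for overlay plotting."""
    out = {}
    for name, vals in groups.items():
        v = np.sort(np.asarray(vals, dtype=float))
        out[name] = (v, np.arange(1, len(v) + 1) / len(v))
    return out
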