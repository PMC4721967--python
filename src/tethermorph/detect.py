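"""Object detection and single-molecule selection on flattened topographs.

Detection thresholds the flattened image at background median plus a
configurable multiple of the median absolute deviation and takes 8-connected
components (molecules are thin, often diagonal curves; 4-connectivity would
fragment them).  Selection then automates the criteria a microscopist
applies by eye: the whole object must lie within the captured field (no part
cropped by the borders), must be an isolated individual molecule rather than
an aggregate, and must be traceable.  Every detected object lands in exactly
one bin — retained, or rejected with a single recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .topograph import Topograph

log = logging.getLogger(__name__)

REASONS = ("none", "border", "aggregate", "untraceable", "too_small")


@dataclass
class ThresholdPolicy:
    """Background + k * MAD height threshold with a minimum object area.

    The MAD is scaled by 1.4826 (sigma-consistent for Gaussian noise), a
    light Gaussian blur (``smooth_sigma_px``) suppresses single-pixel noise
    before thresholding, and ``min_height_nm`` puts an absolute floor on
    the threshold so noise-free images do not threshold at background.
    """

    k_mad: float = 3.0
    k_mad_low: float = 2.0
    min_area_px: int = 30
    mad_scale: float = 1.4826
    high_floor_nm: float = 0.75
    low_floor_nm: float = 0.25

    def foreground(self, heights: np.ndarray) -> np.ndarray:
        """Hysteresis mask: pixels above the low threshold that connect to a
        pixel above the high threshold.  Keeps thin ridges intact and the
        sub-nm gap inside an unwinding bubble open, while isolated noise
        rarely reaches the high threshold."""
        from skimage.filters import apply_hysteresis_threshold
        med = float(np.median(heights))
        sigma = float(np.median(np.abs(heights - med))) * self.mad_scale
        high = med + max(self.k_mad * sigma, self.high_floor_nm)
        low = med + max(self.k_mad_low * sigma, self.low_floor_nm)
        return apply_hysteresis_threshold(heights, low, high)


@dataclass
class DetectedObject:
    object_id: int
    pixel_mask: np.ndarray | None   # full-field boolean mask; None for specks
                                    # below min_area (never traced)
    area_px: int
    bounding_box: tuple[int, int, int, int]   # r0, c0, r1, c1 (exclusive)
    touches_border: bool
    mean_height_nm: float
    rejection_reason: str = "none"

    @property
    def retained(self) -> bool:
        return self.rejection_reason == "none"


@dataclass
class SelectionCriteria:
    """Automated stand-ins for the manual keep/reject judgements."""

    aggregate_area_factor: float = 2.5
    expected_retained_range: tuple[float, float] = (0.40, 0.70)


def detect_objects(topo: Topograph,
                   policy: ThresholdPolicy | None = None) -> list[DetectedObject]:
    """Find candidate molecules as 8-connected components above threshold.

    Components smaller than ``min_area_px`` are returned already rejected
    with reason ``too_small``.  An empty or background-only image yields an
    empty list.
    """
    if topo.provenance != "flattened":
        raise ValueError("detect_objects expects a flattened topograph")
    policy = policy or ThresholdPolicy()
    h = topo.heights
    fg = policy.foreground(h)
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    objects: list[DetectedObject] = []
    if n == 0:
        return objects
    slices = ndimage.find_objects(lab)
    areas = ndimage.sum_labels(fg, lab, index=np.arange(1, n + 1))
    for i, sl in enumerate(slices, start=1):
        area = int(areas[i - 1])
        small = area < policy.min_area_px
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        touches = r0 == 0 or c0 == 0 or r1 == h.shape[0] or c1 == h.shape[1]
        if small:
            mask = None               # speck: never traced, keep it light
            mean_h = float(h[sl][lab[sl] == i].mean())
        else:
            mask = np.zeros_like(fg)
            mask[sl] = lab[sl] == i
            mean_h = float(h[mask].mean())
        objects.append(DetectedObject(
            object_id=i, pixel_mask=mask, area_px=area,
            bounding_box=(r0, c0, r1, c1), touches_border=touches,
            mean_height_nm=mean_h,
            rejection_reason="too_small" if small else "none"))
    return objects


def select_molecules(objects: list[DetectedObject],
                     criteria: SelectionCriteria | None = None,
                     truth_counts: dict[int, int] | None = None,
                     ) -> tuple[list[DetectedObject], list[tuple[int, str]]]:
    """Apply the selection criteria; returns (retained, rejection table).

    ``truth_counts`` optionally maps object_id -> number of ground-truth
    molecules inside the object; objects containing more than one are
    aggregates by construction.  Without truth, aggregates are flagged by
    area relative to the median single-molecule-scale object.  The
    ``untraceable`` reason is assigned later by the tracing stage via
    :func:`mark_untraceable`; here every object is counted exactly once.
    """
    criteria = criteria or SelectionCriteria()
    rejected: list[tuple[int, str]] = []
    survivors: list[DetectedObject] = []
    for obj in objects:
        if obj.rejection_reason == "too_small":
            rejected.append((obj.object_id, "too_small"))
        elif obj.touches_border:
            obj.rejection_reason = "border"
            rejected.append((obj.object_id, "border"))
        else:
            survivors.append(obj)
    areas = np.array([o.area_px for o in survivors], dtype=float)
    med_area = float(np.median(areas)) if len(areas) else 0.0
    retained: list[DetectedObject] = []
    for obj in survivors:
        is_agg = med_area > 0 and obj.area_px > criteria.aggregate_area_factor * med_area
        if truth_counts is not None and truth_counts.get(obj.object_id, 1) > 1:
            is_agg = True
        if is_agg:
            obj.rejection_reason = "aggregate"
            rejected.append((obj.object_id, "aggregate"))
        else:
            retained.append(obj)
    molecule_scale = [o for o in objects if o.rejection_reason != "too_small"]
    if molecule_scale:
        frac = len(retained) / len(molecule_scale)
        lo, hi = criteria.expected_retained_range
        if not lo <= frac <= hi:
            log.warning("retained fraction %.2f outside expected %.2f-%.2f "
                        "(n=%d molecule-scale objects)", frac, lo, hi,
                        len(molecule_scale))
    return retained, rejected


def mark_untraceable(obj: DetectedObject,
                     rejected: list[tuple[int, str]]) -> None:
    """Move a retained object into the rejection table (tracing failed)."""
    obj.rejection_reason = "untraceable"
    rejected.append((obj.object_id, "untraceable"))


def count_truth_molecules(objects: list[DetectedObject],
                          truth_masks: list[np.ndarray],
                          min_overlap_px: int = 5) -> dict[int, int]:
    """Count, per detected object, how many ground-truth molecule footprints
    overlap it by at least ``min_overlap_px`` pixels."""
    counts: dict[int, int] = {}
    for obj in objects:
        if obj.pixel_mask is None:
            counts[obj.object_id] = 0
            continue
        c = 0
        for tm in truth_masks:
            if np.count_nonzero(obj.pixel_mask & tm) >= min_overlap_px:
                c += 1
        counts[obj.object_id] = c
    return counts
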