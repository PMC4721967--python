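"""End-to-end analysis pipeline: flatten -> detect -> select -> trace -> measure.

The pipeline turns raw topographs into a per-molecule metrics table and a
rejection table; with synthetic ground truth supplied, retained molecules
are matched back to their generating records (by footprint overlap) so that
recovery of generator parameters can be evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .anatomy import identify_features
from .detect import (SelectionCriteria, ThresholdPolicy, count_truth_molecules,
                     detect_objects, mark_untraceable, select_molecules)
from .flatten import flatten
from .metrics import molecule_metrics
from .skeleton import UntraceableError, skeletonize_molecule
from .topograph import Topograph

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Everything the analysis stages need, in one reproducible bundle."""

    threshold: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    spur_prune_nm: float = 6.0
    bubble_min_nm: float = 8.0
    height_tie_nm: float = 0.25
    antibody_height_min_nm: float = 3.2
    feature: str = "bubble"          # which feature rel positions refer to
    apply_flatten: bool = True


def analyze_topograph(topo: Topograph, params: AnalysisParams | None = None,
                      truth_masks: list[np.ndarray] | None = None,
                      field_index: int = 0):
    """Analyze one field.  Returns (metrics rows, rejection rows, matches).

    ``matches`` maps each retained object's row index to the index of the
    single overlapping ground-truth mask (when truth is supplied).
    """
    params = params or AnalysisParams()
    if topo.provenance == "raw" and params.apply_flatten:
        topo = flatten(topo)
    objects = detect_objects(topo, params.threshold)
    truth_counts = None
    if truth_masks is not None:
        truth_counts = count_truth_molecules(objects, truth_masks)
    retained, rejected = select_molecules(objects, params.selection, truth_counts)

    rows, matches = [], {}
    for obj in retained:
        try:
            sg = skeletonize_molecule(obj.pixel_mask, topo, obj.object_id,
                                      params.spur_prune_nm)
            anat = identify_features(
                sg, topo, obj.pixel_mask,
                bubble_min_nm=params.bubble_min_nm,
                height_tie_nm=params.height_tie_nm,
                antibody_height_min_nm=params.antibody_height_min_nm)
        except UntraceableError as e:
            log.debug("object %d untraceable: %s", obj.object_id, e)
            mark_untraceable(obj, rejected)
            continue
        m = molecule_metrics(anat, feature=params.feature)
        row = {
            "field_index": field_index,
            "object_id": obj.object_id,
            "total_length_nm": m.total_length_nm,
            "bubble_size_nm": m.bubble_size_nm,
            "norm_splay_distance": m.norm_splay_distance,
            "rel_begin": m.rel_begin,
            "rel_center": m.rel_center,
            "rel_end": m.rel_end,
            "conformation_class": m.conformation_class,
            "orientation_ambiguous": m.orientation_ambiguous,
        }
        for i, name in enumerate(("x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8")):
            row[name] = m.segments.as_tuple()[i]
        if truth_masks is not None:
            overlaps = [ti for ti, tm in enumerate(truth_masks)
                        if np.count_nonzero(obj.pixel_mask & tm) >= 5]
            if len(overlaps) == 1:
                matches[len(rows)] = overlaps[0]
        rows.append(row)
    rej_rows = [{"field_index": field_index, "object_id": oid, "reason": r}
                for oid, r in rejected]
    return rows, rej_rows, matches


def truth_to_frame(truths) -> pd.DataFrame:
    """Flatten GroundTruthRecord objects into a DataFrame."""
    rows = []
    for t in truths:
        d = asdict(t)
        d["bubble_strand_1_nm"], d["bubble_strand_2_nm"] = d.pop("bubble_strand_lengths_nm")
        d["bubble_begin_rel"], d["bubble_end_rel"] = d.pop("bubble_span_rel")
        arms = d.pop("splay_arm_lengths_nm")
        for i in range(4):
            d[f"arm_{i+1}_nm"] = arms[i] if i < len(arms) else 0.0
        d["anchor_x_nm"], d["anchor_y_nm"], d["angle_rad"] = d.pop("placement")
        rows.append(d)
    return pd.DataFrame(rows)


def analyze_population(fields, params: AnalysisParams | None = None,
                       with_truth: bool = False):
    """Analyze a list of generated fields.

    ``fields`` are (Topograph, truths) or (Topograph, truths, masks) tuples
    as produced by :func:`tethermorph.synthetic.generate_population`.
    Returns (metrics DataFrame, rejections DataFrame); when ``with_truth``
    and masks are present, the metrics frame gains ``true_*`` columns from
    the matched ground-truth record.
    """
    params = params or AnalysisParams()
    all_rows, all_rej = [], []
    for fi, item in enumerate(fields):
        topo, truths = item[0], item[1]
        masks = item[2] if len(item) > 2 else None
        rows, rej, matches = analyze_topograph(
            topo, params, truth_masks=masks if with_truth else None,
            field_index=fi)
        if with_truth and masks is not None:
            tf = truth_to_frame(truths)
            for ri, ti in matches.items():
                for col in ("molecule_id", "true_contour_length_nm",
                            "n_splayed_ends", "has_bubble", "class_label",
                            "bubble_strand_1_nm", "bubble_strand_2_nm",
                            "bubble_begin_rel", "bubble_end_rel", "label_rel",
                            "touches_border", "overlaps_other"):
                    out_col = col if col.startswith("true_") else "true_" + col
                    rows[ri][out_col] = tf.iloc[ti][col]
        all_rows.extend(rows)
        all_rej.extend(rej)
    metrics = pd.DataFrame(all_rows)
    rejections = pd.DataFrame(all_rej, columns=["field_index", "object_id", "reason"])
    return metrics, rejections
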