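"""Feature identification and 8-segment measurement."""

import numpy as np
import pytest

from tethermorph.anatomy import SegmentLengths, identify_features, measure_segments
from tethermorph.skeleton import skeletonize_molecule
from tethermorph.synthetic import add_features
from tethermorph.topograph import Topograph
from tests.conftest import clean_scan_spec
from tests.test_skeleton import _render_mask, _shift
from tests.test_synthetic import _backbone, _rod_draw


def _trace(draw, seed=0, backbone_seed=0):
    geom = add_features(_shift(_backbone(seed=backbone_seed), (600, 600)), draw,
                        np.random.default_rng(seed))
    mask, topo = _render_mask(geom)
    sg = skeletonize_molecule(mask, topo)
    return identify_features(sg, topo, mask), geom.truth


class TestSegmentLengths:
    def test_paired_feature_invariants_enforced(self):
        with pytest.raises(ValueError):
            SegmentLengths(x4=10.0, x5=0.0)
        with pytest.raises(ValueError):
            SegmentLengths(x1=5.0)
        with pytest.raises(ValueError):
            SegmentLengths(x3=-1.0)

    def test_flags(self):
        s = SegmentLengths(x1=10, x2=9, x3=100, x4=20, x5=18)
        assert s.n_splayed and s.has_bubble and not s.c_splayed


class TestIdentifyFeatures:
    def test_tall_terminal_cap_labels_the_n_end(self):
        anat, truth = _trace(_rod_draw())
        assert not anat.orientation_ambiguous
        # GFP cap (2.5 nm) must sit at the reported N end
        assert anat.n_end.tip_height_nm > anat.c_end.tip_height_nm

    def test_rod_measures_whole_stalk_in_x3(self):
        anat, truth = _trace(_rod_draw())
        seg = measure_segments(anat)
        assert seg.x3 > 0
        assert seg.as_tuple()[0:2] == (0.0, 0.0)
        assert seg.x4 == seg.x5 == seg.x6 == seg.x7 == seg.x8 == 0.0
        assert seg.x3 == pytest.approx(truth.true_contour_length_nm, rel=0.05)

    def test_bubble_strands_measured_within_ten_percent(self):
        draw = _rod_draw(has_bubble=True, bubble_strand_lengths_nm=(30.0, 24.0))
        anat, truth = _trace(draw, backbone_seed=2)
        seg = measure_segments(anat)
        assert seg.x4 == pytest.approx(30.0, rel=0.10)
        assert seg.x5 == pytest.approx(24.0, rel=0.10)

    def test_segment_sum_recovers_contour_length(self):
        draw = _rod_draw(n_splayed=True, c_splayed=True,
                         arm_lengths_nm=(20.0, 18.0, 22.0, 19.0),
                         has_bubble=True, bubble_strand_lengths_nm=(28.0, 26.0))
        anat, truth = _trace(draw, backbone_seed=4)
        seg = measure_segments(anat)
        total = ((seg.x1 + seg.x2) / 2 + seg.x3 + (seg.x4 + seg.x5) / 2
                 + seg.x6 + (seg.x7 + seg.x8) / 2)
        assert total == pytest.approx(truth.true_contour_length_nm, rel=0.10)

    def test_clean_population_edge_labels_agree_with_truth(self, wt_clean):
        """On the ideal render, traced conformation features agree with the
        generator's anatomy for at least 95% of molecules."""
        metrics, _rej = wt_clean
        matched = metrics.dropna(subset=["true_class_label"])
        assert len(matched) > 150
        agree = (matched["conformation_class"] == matched["true_class_label"]).mean()
        assert agree >= 0.95

    def test_antibody_blob_located_at_label_position(self):
        draw = _rod_draw(label_rel=0.48)
        anat, truth = _trace(draw, backbone_seed=6)
        assert anat.antibody_rel is not None
        lo, mid, hi = anat.antibody_rel
        assert lo <= mid <= hi
        assert mid == pytest.approx(0.48, abs=0.05)

    def test_bubble_detection_rates_on_clean_population(self, wt_clean):
        """Sensitivity >= 90%, false-positive rate <= 5% against truth."""
        metrics, _rej = wt_clean
        m = metrics.dropna(subset=["true_class_label"])
        truly = m[m["true_has_bubble"].astype(bool)]
        falsely = m[~m["true_has_bubble"].astype(bool)]
        assert (truly["bubble_size_nm"] > 0).mean() >= 0.90
        assert (falsely["bubble_size_nm"] > 0).mean() <= 0.05
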