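"""Per-molecule metrics and population statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tethermorph.anatomy import Anatomy, End, SegmentLengths
from tethermorph.metrics import (MoleculeMetrics, PredictionParams, bubble_size,
                                 compare_groups, independent_ends_check,
                                 normalized_splay_distance, percent_shortfall,
                                 predicted_length, relative_positions,
                                 splay_fraction_stats, summarize, total_length)


def make_anatomy(end_a=(0, 0), end_b=(0, 100), path_nm=100.0,
                 arms_n=(0.0, 0.0), arms_c=(0.0, 0.0), strands=(0.0, 0.0),
                 stalk_n=None, stalk_c=0.0, ambiguous=False, px=1.0):
    path = np.array([[0, 0], [0, 1]])
    if stalk_n is None:
        stalk_n = path_nm
    return Anatomy(
        molecule_id=0,
        n_end=End(end_a, arms_n[0] > 0, arms_n),
        c_end=End(end_b, arms_c[0] > 0, arms_c),
        stalk_n_nm=stalk_n, stalk_c_nm=stalk_c,
        bubble_strands_nm=strands, orientation_ambiguous=ambiguous,
        pixel_size_nm=px,
        backbone_path=[("stalk", path, stalk_n)]
        + ([("bubble", path, sum(strands) / 2), ("bubble", path, sum(strands) / 2)]
           if strands[0] else [])
        + ([("stalk", path, stalk_c)] if stalk_c else []))


class TestSegmentArithmetic:
    @pytest.mark.parametrize("x4,x5,expect", [(30, 24, 27), (17, 17, 17), (0, 0, 0)])
    def test_bubble_size(self, x4, x5, expect):
        assert bubble_size(SegmentLengths(x3=10, x4=x4, x5=x5)) == expect

    def test_total_length_rod(self):
        assert total_length(SegmentLengths(x3=145)) == 145

    def test_total_length_full_anatomy(self):
        seg = SegmentLengths(x1=20, x2=20, x3=40, x4=30, x5=24, x6=50,
                             x7=10, x8=10)
        assert total_length(seg) == pytest.approx(147.0)

    @given(st.floats(0.1, 10.0))
    def test_linearity_under_scaling(self, c):
        seg = SegmentLengths(x1=8, x2=6, x3=40, x4=30, x5=24, x6=50, x7=9, x8=7)
        scaled = SegmentLengths(*(v * c for v in seg.as_tuple()))
        assert total_length(scaled) == pytest.approx(c * total_length(seg))
        assert bubble_size(scaled) == pytest.approx(c * bubble_size(seg))


class TestNormalizedSplayDistance:
    def test_straight_rod_is_one(self):
        assert normalized_splay_distance(make_anatomy()) == pytest.approx(1.0, abs=0.02)

    def test_semicircle_is_two_over_pi(self):
        r = 50.0
        anat = make_anatomy(end_a=(0, 0), end_b=(0, 100), path_nm=math.pi * r)
        assert normalized_splay_distance(anat) == pytest.approx(2 / math.pi, abs=0.03)

    def test_tight_hairpin(self):
        anat = make_anatomy(end_a=(0, 0), end_b=(5, 0), path_nm=140.0)
        assert normalized_splay_distance(anat) == pytest.approx(5 / 140, abs=0.005)

    def test_degenerate_coincident_junctions_is_none(self):
        assert normalized_splay_distance(make_anatomy(end_b=(0, 0))) is None

    def test_scale_invariance(self):
        a = make_anatomy(end_a=(0, 0), end_b=(0, 80), path_nm=120.0, px=1.0)
        b = make_anatomy(end_a=(0, 0), end_b=(0, 80), path_nm=120.0 * 3, px=3.0)
        assert normalized_splay_distance(a) == pytest.approx(
            normalized_splay_distance(b))


class TestRelativePositions:
    def test_central_bubble_positions(self):
        anat = make_anatomy(stalk_n=40.0, stalk_c=40.0, strands=(20.0, 20.0))
        assert relative_positions(anat, "bubble") == pytest.approx((0.4, 0.5, 0.6))

    def test_zero_extent_feature_at_n_terminus(self):
        anat = make_anatomy()
        anat.antibody_rel = (0.0, 0.0, 0.0)
        assert relative_positions(anat, "antibody") == (0.0, 0.0, 0.0)

    def test_withheld_when_orientation_ambiguous(self):
        anat = make_anatomy(stalk_n=40.0, stalk_c=40.0, strands=(20.0, 20.0),
                            ambiguous=True)
        assert relative_positions(anat, "bubble") is None

    def test_absent_bubble_is_none(self):
        assert relative_positions(make_anatomy(), "bubble") is None


class TestConformationStats:
    def test_metrics_row_invariants(self):
        with pytest.raises(ValueError):
            MoleculeMetrics(0, 100.0, 0.0, 0.9, None, None, None,
                            "splayN+bubble")   # bubble class but size 0
        with pytest.raises(ValueError):
            MoleculeMetrics(0, 100.0, 20.0, 1.5, None, None, None,
                            "bubble")          # nsd outside (0, 1]

    def test_all_rod_population(self):
        any_s, both_s = splay_fraction_stats(["rod"] * 20)
        assert any_s.fraction == 0.0 and both_s.fraction == 0.0

    def test_single_both_splayed_molecule(self):
        any_s, both_s = splay_fraction_stats(["splayN+splayC"])
        assert any_s.fraction == 1.0 and both_s.fraction == 1.0

    def test_binomial_population_recovers_fractions(self):
        rng = np.random.default_rng(77)
        p = 0.6164
        labels = []
        for _ in range(2000):
            n, c = rng.random() < p, rng.random() < p
            labels.append(("splayN" if n else "") + ("+" if n and c else "")
                          + ("splayC" if c else "") or "rod")
        any_s, both_s = splay_fraction_stats(labels)
        assert any_s.ci_low <= 1 - (1 - p) ** 2 <= any_s.ci_high
        assert both_s.ci_low <= p * p <= both_s.ci_high

    @pytest.mark.parametrize("fb,expect", [(0.38, 0.8528), (0.0, 0.0), (1.0, 1.0)])
    def test_independent_ends_check(self, fb, expect):
        assert independent_ends_check(fb) == pytest.approx(expect, abs=5e-4)

    def test_independent_ends_out_of_range(self):
        with pytest.raises(ValueError):
            independent_ends_check(1.5)


class TestPredictedLengths:
    def test_n_half_construct(self):
        pred = predicted_length(889)
        assert pred == pytest.approx(132.0, abs=0.05)
        assert percent_shortfall(91.2, pred) == pytest.approx(30.9, abs=0.05)

    def test_full_length_vs_predicted_minimum(self):
        assert percent_shortfall(145.0, 204.0) == pytest.approx(28.9, abs=0.05)

    def test_equal_measured_and_predicted(self):
        assert percent_shortfall(132.0, 132.0) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            predicted_length(0)
        with pytest.raises(ValueError):
            percent_shortfall(100.0, 0.0)
        with pytest.raises(ValueError):
            PredictionParams(rise_per_residue_nm=-1.0)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        r = compare_groups([5.0] * 10, [5.0] * 10)
        assert r.p == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(27, 5, 100)
        b = rng.normal(17, 5, 100)
        assert compare_groups(a, b).p < 1e-4

    def test_swapping_groups_flips_t_keeps_p(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(10, 2, 30), rng.normal(12, 3, 30)
        r1, r2 = compare_groups(a, b), compare_groups(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)


class TestSummaries:
    def test_small_set_mean_and_ecdf(self):
        s = summarize([1.0, 2.0, 3.0], bin_width=1.0)
        assert s.mean == 2.0
        assert np.allclose(s.ecdf_fractions, [1 / 3, 2 / 3, 1.0])

    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=60),
           st.sampled_from([0.5, 2.0, 10.0]))
    def test_histogram_counts_conserve_n(self, values, bw):
        s = summarize(values, bin_width=bw)
        assert s.counts.sum() == len(values)
        assert s.ecdf_fractions[-1] == 1.0


def test_bubble_and_antibody_position_ecdfs_overlap(wt_clean, labeled_clean):
    """The bubble sits at the hinge the antibody tags: their relative-center
    ECDFs should be close (two-sample KS distance <= 0.15)."""
    from scipy.stats import ks_2samp
    wt_metrics, _ = wt_clean
    ab_metrics, _ = labeled_clean
    bubble_pos = wt_metrics["rel_center"].dropna()
    ab_pos = ab_metrics["rel_center"].dropna()
    assert len(bubble_pos) >= 80 and len(ab_pos) >= 80
    stat = ks_2samp(bubble_pos, ab_pos).statistic
    assert stat <= 0.15
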