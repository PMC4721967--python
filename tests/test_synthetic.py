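"""Synthetic topograph generator: feature construction, rendering, determinism."""

import dataclasses

import numpy as np
import pytest

from tethermorph.synthetic import (MoleculeDraw, MoleculePopulationSpec,
                                   PlacementError, ScanSpec, add_features,
                                   apply_tip, draw_molecule, generate_population,
                                   get_preset, place_geometries, rasterize_ideal,
                                   render_topograph, sample_backbone,
                                   tip_structure)
from tests.conftest import clean_scan_spec


def _rod_draw(L=145.0, **kw):
    base = dict(contour_length_nm=L, n_splayed=False, c_splayed=False,
                arm_lengths_nm=(0.0, 0.0, 0.0, 0.0), has_bubble=False,
                bubble_strand_lengths_nm=(0.0, 0.0), bubble_center_rel=0.48,
                label_rel=None, has_gfp=True, has_grip=True,
                bubble_lateral_offset_nm=8.0)
    base.update(kw)
    return MoleculeDraw(**base)


def _backbone(L=145.0, seed=0):
    return sample_backbone(L, 1e6, 2.0, np.random.default_rng(seed))


class TestAddFeatures:
    def test_degenerate_draw_is_single_polyline_rod(self):
        geom = add_features(_backbone(), _rod_draw(), np.random.default_rng(0))
        assert [k for _p, k in geom.polylines] == ["stalk"]
        assert geom.truth.class_label == "rod"
        assert {k for *_c, k in geom.disks} == {"gfp", "grip"}

    def test_bubble_strand_lengths_pass_through_to_truth(self):
        draw = _rod_draw(has_bubble=True, bubble_strand_lengths_nm=(30.0, 24.0))
        geom = add_features(_backbone(), draw, np.random.default_rng(0))
        assert geom.truth.bubble_strand_lengths_nm == (30.0, 24.0)
        kinds = [k for _p, k in geom.polylines]
        assert kinds.count("bubble_strand") == 2

    def test_splay_incidence_matches_binomial_algebra(self):
        """With per-end probability p = 0.6164, the fraction with at least
        one splayed end should match 1 - (1-p)^2 = 0.853 within a binomial
        95% band at n = 1000."""
        spec = MoleculePopulationSpec()
        rng = np.random.default_rng(1234)
        draws = [draw_molecule(spec, rng) for _ in range(1000)]
        frac = np.mean([d.n_splayed or d.c_splayed for d in draws])
        p = spec.splay_prob_per_end
        expected = 1 - (1 - p) ** 2
        assert abs(frac - expected) < 2.0 * np.sqrt(expected * (1 - expected) / 1000)

    def test_geometry_conserves_contour_length(self):
        """Averaged-feature polyline length equals the recorded ground-truth
        contour within two pixel lengths."""
        px = ScanSpec().pixel_size_nm
        rng = np.random.default_rng(7)
        spec = MoleculePopulationSpec()
        for _ in range(20):
            d = draw_molecule(spec, rng)
            geom = add_features(sample_backbone(d.contour_length_nm, 50.0, 2.0, rng),
                                d, rng)
            total = 0.0
            for pts, kind in geom.polylines:
                ln = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
                total += ln / 2.0 if kind in ("bubble_strand", "arm_n", "arm_c") else ln
            assert abs(total - geom.truth.true_contour_length_nm) <= 2 * px


class TestRender:
    def test_zero_tip_zero_noise_render_is_the_ideal_map(self):
        scan = clean_scan_spec()
        rng = np.random.default_rng(0)
        geom = add_features(_backbone(), _rod_draw(), rng)
        placed = place_geometries([geom], scan, np.random.default_rng(1))
        topo, truths = render_topograph(placed, scan, np.random.default_rng(2))
        ideal = rasterize_ideal(placed, scan)
        assert np.array_equal(topo.heights, ideal)

    def test_tip_dilation_matches_brute_force_neighborhood_max(self):
        px = 1.5
        rng = np.random.default_rng(3)
        surf = np.zeros((64, 64))
        surf[rng.integers(0, 64, 40), rng.integers(0, 64, 40)] = rng.uniform(
            0.5, 2.5, 40)
        for tip in (2.0, 4.0):
            elem = tip_structure(tip, px)
            r = elem.shape[0] // 2
            pad = np.pad(surf, r)
            brute = np.empty_like(surf)
            for i in range(64):
                for j in range(64):
                    brute[i, j] = np.max(pad[i:i + 2 * r + 1, j:j + 2 * r + 1] + elem)
            brute = np.maximum(brute, surf)
            assert np.array_equal(apply_tip(surf, tip, px), brute)

    def test_peak_height_preserved_and_width_monotone_in_tip_radius(self):
        """A larger tip broadens an isolated cap laterally but cannot raise
        or lower its apex (sampled finely enough to resolve the broadening)."""
        px = 0.5
        n, c = 128, 64
        yy, xx = np.mgrid[0:n, 0:n]
        d = np.hypot(yy - c, xx - c) * px
        r0, h0 = 6.0, 2.0
        H = np.where(d <= r0, h0 * np.sqrt(np.clip(1 - (d / r0) ** 2, 0, 1)), 0.0)

        def fwhm(img):
            return (img[c] >= h0 / 2).sum()

        out2 = apply_tip(H, 2.0, px)
        out5 = apply_tip(H, 5.0, px)
        assert np.isclose(out2.max(), H.max())
        assert np.isclose(out5.max(), H.max())
        assert fwhm(out5) > fwhm(out2) >= fwhm(H)

    def test_oversized_geometry_raises_placement_error(self):
        scan = clean_scan_spec()
        geom = add_features(
            np.column_stack([np.linspace(0, 3 * scan.field_size_nm, 400),
                             np.zeros(400)]),
            _rod_draw(L=3 * scan.field_size_nm), np.random.default_rng(0))
        with pytest.raises(PlacementError):
            place_geometries([geom], scan, np.random.default_rng(1))


class TestPopulation:
    def test_same_seed_gives_identical_ground_truth(self):
        spec = dataclasses.replace(get_preset("wt"), n_molecules=12, seed=5)
        scan = clean_scan_spec()
        a = generate_population(spec, scan)
        b = generate_population(spec, scan)
        ta = [t for _f, ts in a for t in ts]
        tb = [t for _f, ts in b for t in ts]
        assert ta == tb
        for (fa, _), (fb, _) in zip(a, b):
            assert np.array_equal(fa.heights, fb.heights)

    def test_zero_molecules_gives_background_only_field(self):
        spec = MoleculePopulationSpec(n_molecules=0)
        fields = generate_population(spec, clean_scan_spec())
        assert len(fields) == 1
        topo, truths = fields[0]
        assert truths == []
        assert np.all(topo.heights == 0)

    def test_presets_differ_only_in_documented_fields(self):
        wt, dh = get_preset("wt"), get_preset("dhinge")
        differing = {f.name for f in dataclasses.fields(wt)
                     if getattr(wt, f.name) != getattr(dh, f.name)}
        assert differing == {"contour_length_mean_nm", "contour_length_sd_nm",
                             "persistence_length_nm", "bubble_prob",
                             "bubble_strand_length_mean_nm",
                             "bubble_strand_length_sd_nm",
                             "bubble_strand_asym_sd_nm"}
        assert dh.bubble_prob == 0.2
        assert dh.bubble_strand_length_mean_nm == 17.0
        assert wt.bubble_prob == 0.5
        assert wt.splay_prob_per_end == 0.6164

    def test_reduced_condition_preset_suppresses_splays_and_bubbles(self):
        nd = get_preset("noDTT")
        wt = get_preset("wt")
        assert nd.splay_prob_per_end < 0.2 * wt.splay_prob_per_end
        assert nd.bubble_prob < 0.2 * wt.bubble_prob
        assert nd.persistence_length_nm > 10 * wt.persistence_length_nm
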