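"""Skeleton tracing: path lengths, graph structure, untraceable cases."""

import math

import numpy as np
import pytest

from tethermorph.skeleton import (PathError, UntraceableError, path_length,
                                  skeletonize_molecule)
from tethermorph.synthetic import add_features, sample_backbone
from tethermorph.topograph import Topograph
from tests.conftest import clean_scan_spec
from tests.test_synthetic import _backbone, _rod_draw


class TestPathLength:
    def test_axial_steps(self):
        path = np.column_stack([np.full(11, 5), np.arange(11)])
        assert path_length(path, 2.0) == pytest.approx(20.0)

    def test_diagonal_steps(self):
        path = np.column_stack([np.arange(11), np.arange(11)])
        assert path_length(path, 2.0) == pytest.approx(20 * math.sqrt(2))

    def test_non_adjacent_pixels_raise(self):
        with pytest.raises(PathError):
            path_length(np.array([[0, 0], [0, 2]]), 1.0)

    def test_too_short_path_raises(self):
        with pytest.raises(PathError):
            path_length(np.array([[0, 0]]), 1.0)

    def test_digital_circle_close_to_circumference(self):
        from skimage.draw import circle_perimeter
        rr, cc = circle_perimeter(100, 100, 30)
        order = np.argsort(np.arctan2(rr - 100.0, cc - 100.0))
        path = np.stack([rr[order], cc[order]], axis=1)
        keep = np.concatenate([[True], (np.diff(path, axis=0) != 0).any(axis=1)])
        path = np.concatenate([path[keep], path[keep][:1]])
        L = path_length(path, 1.0)
        assert abs(L / (60 * math.pi) - 1.0) < 0.05


def _render_mask(geom, scan=None):
    from tethermorph.synthetic import rasterize_ideal
    scan = scan or clean_scan_spec()
    H = rasterize_ideal([geom], scan)
    return H > 0, Topograph(H, scan.pixel_size_nm, "flattened")


def _shift(backbone, offset):
    return backbone - backbone.mean(axis=0) + np.asarray(offset, float)


class TestSkeletonGraph:
    def test_straight_rod_is_one_edge_two_endpoints(self):
        geom = add_features(_shift(_backbone(), (600, 600)), _rod_draw(),
                            np.random.default_rng(0))
        mask, topo = _render_mask(geom)
        sg = skeletonize_molecule(mask, topo)
        assert len(sg.endpoints) == 2
        assert sg.graph.number_of_edges() == 1
        assert sg.n_cycles() == 0

    def test_both_splayed_bubble_molecule_has_one_cycle_four_endpoints(self):
        draw = _rod_draw(n_splayed=True, c_splayed=True,
                         arm_lengths_nm=(20.0, 18.0, 22.0, 19.0),
                         has_bubble=True, bubble_strand_lengths_nm=(28.0, 26.0))
        geom = add_features(_shift(_backbone(seed=4), (600, 600)), draw,
                            np.random.default_rng(1))
        mask, topo = _render_mask(geom)
        sg = skeletonize_molecule(mask, topo)
        assert sg.n_cycles() == 1
        assert len(sg.endpoints) == 4

    def test_crossing_rods_are_untraceable_downstream(self):
        """Two rods crossing produce >4 endpoints; the anatomy parser must
        refuse them."""
        from tethermorph.anatomy import identify_features
        scan = clean_scan_spec()
        h = np.zeros((scan.resolution_px,) * 2)
        h[200, 100:300] = 1.5
        h[120:280, 200] = 1.5
        topo = Topograph(h, scan.pixel_size_nm, "flattened")
        sg = skeletonize_molecule(h > 0, topo)
        with pytest.raises(UntraceableError):
            identify_features(sg, topo)

    def test_edge_length_bounded_below_by_euclidean_distance(self, wt_clean):
        """Triangle inequality: each traced edge's path length is at least
        the straight-line distance between its end nodes."""
        from tethermorph.detect import detect_objects, select_molecules
        from tethermorph.flatten import flatten as fl
        from tethermorph.synthetic import (MoleculePopulationSpec,
                                           generate_population)
        pop = MoleculePopulationSpec(n_molecules=10, seed=2)
        fields = generate_population(pop, clean_scan_spec())
        checked = 0
        for topo, _t in fields:
            ft = fl(topo)
            retained, _ = select_molecules(detect_objects(ft))
            for obj in retained:
                try:
                    sg = skeletonize_molecule(obj.pixel_mask, ft)
                except UntraceableError:
                    continue
                for u, v, d in sg.graph.edges(data=True):
                    eu = math.hypot(u[0] - v[0], u[1] - v[1]) * sg.pixel_size_nm
                    assert d["length_nm"] >= eu - 1e-9
                    checked += 1
        assert checked > 5

    def test_short_spurs_are_pruned(self):
        scan = clean_scan_spec()
        h = np.zeros((scan.resolution_px,) * 2)
        h[200, 100:300] = 1.5
        h[198:200, 150] = 1.5          # 2-px spur (~4.7 nm < 6 nm prune)
        topo = Topograph(h, scan.pixel_size_nm, "flattened")
        sg = skeletonize_molecule(h > 0, topo, spur_prune_nm=6.0)
        assert len(sg.endpoints) == 2
        assert sg.graph.number_of_edges() == 1
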