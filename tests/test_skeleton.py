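"""Thinning, skeleton graphs, pruning, fibril/cross-link classification."""

import numpy as np
import pytest

from wallfibril3d.experiments import euler_betti
from wallfibril3d.segmentation import threshold_segment
from wallfibril3d.skeleton import (ClassifyParams, build_skeleton_graph,
                                   classify_segments, prune_spurs, thin3d)
from wallfibril3d.volume import DensityVolume

VS = 0.87


class TestThin3d:
    def test_single_voxel_survives(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        skel = thin3d(mask)
        assert skel.sum() == 1 and skel[2, 2, 2]

    def test_empty_mask(self):
        assert thin3d(np.zeros((5, 5, 5), bool)).sum() == 0

    def test_rod_reduces_to_path_with_correct_endpoints(self):
        mask = np.zeros((9, 26, 9), bool)
        mask[3:6, 3:23, 3:6] = True  # 3x3x20 solid rod
        skel = thin3d(mask)
        b0, b1 = euler_betti(skel)
        assert (b0, b1) == (1, 0)
        vox = np.argwhere(skel)
        # endpoints within one voxel of the rod end-face centres (4, y, 4)
        lo = vox[vox[:, 1].argmin()]
        hi = vox[vox[:, 1].argmax()]
        assert np.abs(lo - np.array([4, 3, 4])).max() <= 1
        assert np.abs(hi - np.array([4, 22, 4])).max() <= 1

    def test_torus_keeps_its_loop(self):
        z, y, x = np.mgrid[-10:11, -10:11, -10:11]
        torus = ((np.sqrt(y ** 2 + x ** 2) - 7) ** 2 + z ** 2) <= 9
        skel = thin3d(torus)
        assert euler_betti(torus) == euler_betti(skel) == (1, 1)

    def test_branches_survive_geometrically(self):
        # an H of two cylinders and a bridge keeps all four arms
        z, y, x = np.mgrid[0:40, 0:60, 0:24]
        cyl1 = ((z - 11.5) ** 2 + (x - 12) ** 2) <= 3.3 ** 2
        cyl2 = ((z - 23) ** 2 + (x - 12) ** 2) <= 3.3 ** 2
        bridge = (np.abs(y - 30) <= 1.5) & (np.abs(x - 12) <= 1.5) & (z > 11.5) & (z < 23)
        skel = thin3d(cyl1 | cyl2 | bridge)
        vox = np.argwhere(skel)
        for zc in (12, 23):
            arm = vox[np.abs(vox[:, 0] - zc) <= 1]
            assert arm[:, 1].min() <= 5 and arm[:, 1].max() >= 54


class TestSkeletonGraph:
    def test_straight_path(self):
        skel = np.zeros((5, 24, 5), bool)
        skel[2, 2:22, 2] = True  # 20 voxels
        sg = build_skeleton_graph(skel, VS)
        assert sg.n_nodes == 2 and sg.n_edges == 1
        (_, _, data), = sg.graph.edges(data=True)
        assert data["length_nm"] == pytest.approx(19 * VS)
        assert abs(data["orientation"][1]) == pytest.approx(1.0)

    def test_t_junction(self):
        skel = np.zeros((5, 21, 21), bool)
        skel[2, 2:19, 10] = True
        skel[2, 10, 10:19] = True
        sg = build_skeleton_graph(skel, VS)
        assert sg.n_nodes == 4   # three tips + one clustered junction
        assert sg.n_edges == 3

    def test_isolated_cycle_gets_artificial_node(self):
        skel = np.zeros((5, 15, 15), bool)
        ring = [(3, 5), (3, 6), (3, 7), (3, 8), (4, 9), (5, 10), (6, 10), (7, 10),
                (8, 9), (9, 8), (9, 7), (9, 6), (9, 5), (8, 4), (7, 3), (6, 3),
                (5, 3), (4, 4)]
        for yy, xx in ring:
            skel[2, yy, xx] = True
        sg = build_skeleton_graph(skel, VS)
        assert sg.n_nodes == 1 and sg.n_edges == 1
        (u, v, _), = sg.graph.edges(data=True)
        assert u == v  # self-edge

    def test_rejects_solid_blocks(self):
        solid = np.zeros((7, 7, 7), bool)
        solid[1:6, 1:6, 1:6] = True
        with pytest.raises(ValueError, match="not a skeleton"):
            build_skeleton_graph(solid, VS)


class TestPruneSpurs:
    def _twig_graph(self):
        skel = np.zeros((5, 21, 9), bool)
        skel[2, 2:19, 4] = True
        skel[2, 10, 5:7] = True  # 2-voxel twig
        return build_skeleton_graph(skel, VS)

    def test_zero_min_len_identity(self):
        sg = self._twig_graph()
        out = prune_spurs(sg, 0.0)
        assert out.n_edges == sg.n_edges

    def test_short_twig_removed_and_path_merged(self):
        out = prune_spurs(self._twig_graph(), 5 * VS)
        assert out.n_edges == 1
        assert out.n_nodes == 2

    def test_longest_edge_protected(self):
        # every edge shorter than min_len: the component must not vanish
        skel = np.zeros((5, 9, 9), bool)
        skel[2, 2:7, 4] = True  # 5-voxel path
        sg = build_skeleton_graph(skel, VS)
        out = prune_spurs(sg, 1000.0)
        assert out.n_edges >= 1


class TestClassify:
    def test_two_cylinders_one_bridge(self, two_cylinder_bridge):
        vol, truth, spec = two_cylinder_bridge
        labels = threshold_segment(vol, 0.5)
        sg = prune_spurs(build_skeleton_graph(thin3d(labels), VS), 4 * VS)
        fibrils, links = classify_segments(sg, labels)
        assert len(fibrils) == 2
        assert len(links) == 1
        link = links.crosslinks[0]
        assert {link.fibril_i, link.fibril_j} == {0, 1}
        assert link.length_nm == pytest.approx(5.0, abs=VS)

    def test_fibril_diameters_from_distance_transform(self, two_cylinder_bridge):
        vol, truth, spec = two_cylinder_bridge
        labels = threshold_segment(vol, 0.5)
        sg = prune_spurs(build_skeleton_graph(thin3d(labels), VS), 4 * VS)
        fibrils, _ = classify_segments(sg, labels)
        for f in fibrils:
            assert np.median(f.radii) == pytest.approx(2.5, abs=0.5 * VS)

    def test_layers_assigned(self, two_cylinder_bridge):
        vol, truth, spec = two_cylinder_bridge
        labels = threshold_segment(vol, 0.5)
        sg = prune_spurs(build_skeleton_graph(thin3d(labels), VS), 4 * VS)
        fibrils, _ = classify_segments(sg, labels)
        assert sorted(f.layer_index for f in fibrils) == [0, 1]

    def test_isolated_short_segment_unclassified(self):
        data = np.zeros((16, 20, 16), np.float32)
        data[8, 5:12, 8] = 1.0  # ~6 nm segment, attached to nothing
        labels = threshold_segment(DensityVolume(data, VS), 0.5)
        sg = build_skeleton_graph(thin3d(labels), VS)
        fibrils, links = classify_segments(sg, labels)
        assert len(fibrils) == 0
        assert len(links) == 0
        assert links.n_unclassified >= 1

    def test_empty_graph(self):
        labels = threshold_segment(DensityVolume(np.zeros((10, 10, 10), np.float32), VS), 0.5)
        sg = build_skeleton_graph(thin3d(labels), VS)
        fibrils, links = classify_segments(sg, labels)
        assert len(fibrils) == 0 and len(links) == 0


class TestTopologyPreservation:
    def test_random_masks_components_and_loops(self):
        from wallfibril3d.experiments import topology_preservation

        result = topology_preservation(seed=1, n_masks=50)
        assert result["mismatches"] == 0

    def test_noiseless_phantom_recall_and_radii(self, small_cryo_phantom):
        from wallfibril3d.phantom import _axis_point
        from wallfibril3d.segmentation import clean_components, normalize_density

        vol, truth, spec = small_cryo_phantom
        labels = clean_components(threshold_segment(
            normalize_density(vol), 0.03), 27)
        sg = prune_spurs(build_skeleton_graph(thin3d(labels), VS), 5.0)
        fibrils, _ = classify_segments(sg, labels)
        matched = 0
        for t in truth.fibrils:
            for f in fibrils:
                mids = f.polyline[:: max(len(f.polyline) // 8, 1)]
                d = [np.linalg.norm((p - _axis_point(t, p[1]))[[0, 2]]) for p in mids]
                cover = np.mean(np.array(d) < 2 * VS)
                if cover >= 0.7 and f.length_nm >= 0.5 * t.length:
                    matched += 1
                    break
        assert matched / len(truth.fibrils) >= 0.9
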