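"""Skeletonization, path tracing, gap connection and lumen refinement."""

import heapq
import itertools

import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from angiorecon import phantoms as ph
from angiorecon.centerline import (DistanceField, connect_and_extend,
                                   principal_centerlines, prune_spurs,
                                   refine_with_lumen, skeletonize, trace_path)
from angiorecon.metrics import centerline_accuracy, mcd
from angiorecon.types import Centerline, VesselMask

from conftest import visible_mask


def dijkstra_oracle(field, spacing, start, end, eps=0.1):
    """Brute-force Dijkstra over every voxel; edge u->v costs
    ||step|| / (field[v] + eps). Independent of the implementation."""
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    sp = np.asarray(spacing)
    dist = {tuple(start): 0.0}
    pq = [(0.0, tuple(start))]
    done = set()
    while pq:
        d, u = heapq.heappop(pq)
        if u in done:
            continue
        done.add(u)
        if u == tuple(end):
            return d
        for o in offs:
            v = tuple(np.asarray(u) + o)
            if any(c < 0 or c >= field.shape[i] for i, c in enumerate(v)):
                continue
            nd = d + np.linalg.norm(np.asarray(o) * sp) / (field[v] + eps)
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(pq, (nd, v))
    return np.inf


class TestSkeletonize:
    def test_nodes_subset_of_mask(self, straight_sample):
        sk = skeletonize(straight_sample.mask, "CCA")
        binary = straight_sample.mask.binary("CCA")
        assert all(binary[n] for n in sk.graph.nodes)

    def test_straight_cylinder_skeleton_near_axis(self):
        sample = ph.generate_phantom(ph.straight_tube_spec(radius_mm=4.0))
        sk = skeletonize(sample.mask, "CCA")
        axis_xy = sample.centerlines[0].points[0][:2]
        sp = np.asarray(sample.mask.spacing[:2])
        for node in sk.graph.nodes:
            assert np.linalg.norm(np.asarray(node[:2]) * sp - axis_xy) <= \
                1.0 * max(sample.mask.spacing)

    def test_empty_label_gives_empty_graph(self, straight_sample):
        sk = skeletonize(straight_sample.mask, "PCA")
        assert sk.n_nodes == 0

    def test_y_junction_single_degree3_node(self):
        sample = ph.generate_phantom(ph.y_bifurcation_spec(same_label=True))
        sk = skeletonize(sample.mask, "ICA")
        pruned = prune_spurs(sk, prune_len_mm=3.0)
        degrees = [d for _, d in pruned.graph.degree]
        assert degrees.count(3) == 1
        assert max(degrees) == 3


class TestPrincipalCenterlines:
    def test_straight_tube_single_line_full_length(self, straight_sample):
        sk = skeletonize(straight_sample.mask, "CCA")
        lines = principal_centerlines(sk, straight_sample.mask)
        assert len(lines) == 1
        assert lines[0].length == pytest.approx(40.0, rel=0.05)
        # oriented inferior -> superior
        assert lines[0].points[-1, 2] > lines[0].points[0, 2]

    def test_empty_skeleton_empty_list(self, straight_sample):
        sk = skeletonize(straight_sample.mask, "PCA")
        assert principal_centerlines(sk, straight_sample.mask) == []

    def test_two_disjoint_tubes_get_sides(self):
        sample = ph.generate_phantom(ph.bilateral_spec(noise=0.0))
        sk = skeletonize(sample.mask, "ICA")
        lines = principal_centerlines(sk, sample.mask)
        assert len(lines) == 2
        mid = (sample.mask.shape[0] - 1) * sample.mask.spacing[0] / 2
        for ln in lines:
            expect = "left" if ln.points[:, 0].mean() > mid else "right"
            assert ln.side == expect

    def test_cyclic_skeleton_broken_with_warning(self):
        # a closed square loop of tube, same label
        grid, c = 48, 24.0
        pts = np.array([[12, c, 12], [36, c, 12], [36, c, 36],
                        [12, c, 36], [12, c, 12.0]])
        data = np.zeros((grid,) * 3, np.uint8)
        idx = np.indices(data.shape).reshape(3, -1).T.astype(float)
        for a, b in zip(pts[:-1], pts[1:]):
            d = b - a
            t = np.clip((idx - a) @ d / (d @ d), 0, 1)
            dist = np.linalg.norm(idx - (a + t[:, None] * d), axis=1)
            data.ravel()[dist <= 2.5] = 2            # ICA
        mask = VesselMask(data, (1.0, 1.0, 1.0))
        sk = skeletonize(mask, "ICA")
        with pytest.warns(UserWarning, match="cycl"):
            lines = principal_centerlines(sk, mask)
        assert lines, "loop should still yield at least one path"


class TestTracePath:
    def test_straight_tube_path_on_axis(self, straight_sample):
        field = DistanceField.from_mask(straight_sample.mask)
        line = straight_sample.centerlines[0]
        res = trace_path(field, line.points[0], line.points[-1])
        assert res.traceable
        dev = np.abs(res.line.points[:, :2] - line.points[0][:2]).max()
        assert dev <= max(straight_sample.mask.spacing)

    def test_start_equals_end(self, straight_sample):
        field = DistanceField.from_mask(straight_sample.mask)
        p = straight_sample.centerlines[0].points[0]
        res = trace_path(field, p, p)
        assert res.traceable
        assert res.line.n_points == 1
        assert res.line.length == 0.0
        assert res.cost == 0.0

    def test_cost_budget_yields_untraceable(self, straight_sample):
        field = DistanceField.from_mask(straight_sample.mask)
        line = straight_sample.centerlines[0]
        res = trace_path(field, line.points[0], line.points[-1], max_cost=1e-6)
        assert not res.traceable
        assert res.reason is not None

    def test_handset_field_matches_oracle(self):
        field = np.full((10, 10, 10), 0.5)
        field[5, :, 5] = 4.0                      # a cheap corridor
        df = DistanceField(field, (1.0, 1.0, 1.0))
        res = trace_path(df, (5.0, 0.0, 5.0), (5.0, 9.0, 5.0))
        oracle = dijkstra_oracle(field, (1, 1, 1), (5, 0, 5), (5, 9, 5))
        assert res.cost == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_grids_match_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 13, size=3))
        field = rng.uniform(0.05, 5.0, shape)
        spacing = tuple(rng.uniform(0.5, 2.0, size=3))
        start = rng.integers(0, shape)
        end = rng.integers(0, shape)
        df = DistanceField(field, spacing)
        res = trace_path(df, start * np.asarray(spacing),
                         end * np.asarray(spacing))
        oracle = dijkstra_oracle(field, spacing, start, end)
        assert res.cost == pytest.approx(oracle, abs=1e-9)


class TestConnectAndExtend:
    def test_occlusion_gap_bridged(self, occluded_sample):
        vis = visible_mask(occluded_sample)
        lines = principal_centerlines(skeletonize(vis, "ICA"), vis)
        assert len(lines) == 2
        field = DistanceField.from_mask(vis)
        out = connect_and_extend(lines, field)
        assert len(out) == 1
        assert out[0].complete
        assert out[0].bridged
        truth = occluded_sample.centerlines[0]
        assert mcd(truth, out[0]) <= max(occluded_sample.mask.spacing)
        # the bridged span lies within the 2-voxel-dilated true lumen
        dil = binary_dilation(occluded_sample.mask.binary("ICA"), iterations=2)
        sp = np.asarray(occluded_sample.mask.spacing)
        for s, e in out[0].bridged:
            vox = np.rint(out[0].points[s:e + 1] / sp).astype(int)
            assert dil[vox[:, 0], vox[:, 1], vox[:, 2]].all()

    def test_gap_free_input_nearly_unchanged(self, straight_sample):
        lines = principal_centerlines(skeletonize(straight_sample.mask, "CCA"),
                                      straight_sample.mask)
        field = DistanceField.from_mask(straight_sample.mask)
        out = connect_and_extend(lines, field)
        assert len(out) == len(lines)
        assert mcd(lines[0], out[0]) <= 0.5 * max(straight_sample.mask.spacing)

    def test_wide_gap_left_unbridged_and_flagged(self):
        # two collinear ICA stubs separated by far more than max_bridge
        a = Centerline(np.array([[32.0, 32, 5], [32, 32, 15]]), "ICA")
        b = Centerline(np.array([[32.0, 32, 45], [32, 32, 55]]), "ICA")
        data = np.zeros((64, 64, 64), np.uint8)
        data[30:34, 30:34, 5:16] = 2
        data[30:34, 30:34, 45:56] = 2
        field = DistanceField.from_mask(VesselMask(data, (1.0, 1.0, 1.0)))
        out = connect_and_extend([a, b], field, max_bridge_mm=10.0,
                                 extend=False)
        assert len(out) == 2
        assert not any(ln.complete for ln in out)

    def test_label_and_side_conserved(self, occluded_sample):
        vis = visible_mask(occluded_sample)
        lines = principal_centerlines(skeletonize(vis, "ICA"), vis)
        field = DistanceField.from_mask(vis)
        out = connect_and_extend(lines, field)
        assert {ln.label for ln in out} == {"ICA"}
        assert {ln.side for ln in out} == {lines[0].side}


class TestRefineWithLumen:
    def test_offset_line_recentered(self, straight_sample):
        truth = straight_sample.centerlines[0]
        offset = Centerline(truth.points + np.array([2.0, 0.0, 0.0]), "CCA")
        refined = refine_with_lumen(offset, straight_sample.mask)
        dev = np.linalg.norm(refined.points[2:-2, :2] - truth.points[0][:2],
                             axis=1).max()
        assert dev <= 0.5 * max(straight_sample.mask.spacing)

    def test_centered_line_is_fixed_point(self, straight_sample):
        truth = straight_sample.centerlines[0]
        refined = refine_with_lumen(truth, straight_sample.mask)
        dev = np.linalg.norm(refined.points - truth.points, axis=1).max()
        assert dev <= 0.25 * max(straight_sample.mask.spacing)

    def test_mostly_outside_refused_with_warning(self, straight_sample):
        far = Centerline(straight_sample.centerlines[0].points
                         + np.array([20.0, 0, 0]), "CCA")
        with pytest.warns(UserWarning, match="refus"):
            refined = refine_with_lumen(far, straight_sample.mask)
        assert np.array_equal(refined.points, far.points)

    def test_bridged_span_not_recentered(self, occluded_sample):
        vis = visible_mask(occluded_sample)
        lines = principal_centerlines(skeletonize(vis, "ICA"), vis)
        field = DistanceField.from_mask(vis)
        joined = connect_and_extend(lines, field)[0]
        refined = refine_with_lumen(joined, vis)
        s, e = refined.bridged[0]
        assert np.array_equal(refined.points[s + 1:e], joined.points[s + 1:e])


class TestEndToEndGeometry:
    def test_truth_mask_recovery(self, y_sample):
        mask = y_sample.mask
        lines = []
        for label in mask.labels_present():
            lines.extend(principal_centerlines(skeletonize(mask, label), mask))
        field = DistanceField.from_mask(mask)
        lines = connect_and_extend(lines, field)
        lines = [refine_with_lumen(ln, mask) for ln in lines]
        for truth in y_sample.centerlines:
            best = min((ln for ln in lines if ln.label == truth.label),
                       key=lambda ln: mcd(truth, ln))
            assert mcd(truth, best) <= max(mask.spacing)
            assert centerline_accuracy(best, truth, tol_mm=1.0) >= 0.95
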