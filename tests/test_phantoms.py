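"""Phantom generator and augmentation suite."""

import math

import numpy as np
import pytest

from angiorecon import phantoms as ph
from angiorecon.types import SEQUENCE_KINDS


def exact_capsule_mask(p0, p1, radius, shape, spacing):
    """Oracle: exact Euclidean distance of voxel centres to the segment,
    with flat end caps (projection clamped to the segment interior)."""
    idx = np.indices(shape).reshape(3, -1).T * np.asarray(spacing)
    d = p1 - p0
    L2 = d @ d
    t = (idx - p0) @ d / L2
    closest = p0 + np.clip(t, 0, 1)[:, None] * d
    dist = np.linalg.norm(idx - closest, axis=1)
    inside = (dist <= radius) & (t >= 0) & (t <= 1)
    return inside.reshape(shape)


class TestGeneratePhantom:
    def test_cylinder_volume_close_to_analytic(self, straight_sample):
        n = int((straight_sample.mask.data > 0).sum())
        analytic = math.pi * 3.0**2 * 40.0
        assert abs(n - analytic) / analytic < 0.10

    def test_cylinder_matches_exact_rasterization_oracle(self, straight_sample):
        line = straight_sample.centerlines[0]
        oracle = exact_capsule_mask(line.points[0], line.points[-1], 3.0,
                                    straight_sample.mask.shape,
                                    straight_sample.mask.spacing)
        got = straight_sample.mask.data > 0
        # identical up to sub-voxel boundary ties of the polyline sampling
        diff = int(np.logical_xor(oracle, got).sum())
        assert diff <= 0.005 * oracle.size
        assert abs(int(oracle.sum()) - int(got.sum())) <= 0.02 * oracle.sum()

    def test_deterministic_given_seed(self):
        spec = ph.straight_tube_spec(noise=5.0, seed=11)
        a = ph.generate_phantom(spec)
        b = ph.generate_phantom(ph.straight_tube_spec(noise=5.0, seed=11))
        for kind in SEQUENCE_KINDS:
            assert np.array_equal(a.volumes[kind].data, b.volumes[kind].data)
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_sequence_contrast(self, straight_sample):
        fg = straight_sample.mask.data > 0
        tof = straight_sample.volumes["TOF"].data
        t1 = straight_sample.volumes["T1WI"].data
        assert tof[fg].mean() > tof[~fg].mean()        # bright lumen on TOF
        assert t1[fg].mean() < t1[~fg].mean()          # dark lumen on black-blood

    def test_occlusion_contrast(self, occluded_sample):
        occ = occluded_sample.occluded
        assert occ.any()
        tof = occluded_sample.volumes["TOF"].data
        t1 = occluded_sample.volumes["T1WI"].data
        bg = ph.DEFAULT_BACKGROUND
        assert tof[occ].mean() == pytest.approx(bg["TOF"], abs=1e-6)
        assert abs(t1[occ].mean() - bg["T1WI"]) > 10.0
        # occluded span still labelled in the ground-truth mask
        assert (occluded_sample.mask.data[occ] > 0).all()

    def test_branch_exits_grid_names_branch(self):
        spec = ph.straight_tube_spec()
        spec.branches[0].control_points[:, 0] += 100.0
        with pytest.raises(ValueError, match="CCA"):
            ph.generate_phantom(spec)

    def test_overlapping_labels_rejected(self):
        spec = ph.straight_tube_spec(label="CCA")
        other = ph.straight_tube_spec(label="ICA")
        spec.branches.append(other.branches[0])
        with pytest.raises(ValueError, match="overlaps"):
            ph.generate_phantom(spec)

    def test_occlusion_span_outside_arc_rejected(self):
        spec = ph.straight_tube_spec()
        spec.branches[0].occlusion_span = (30.0, 90.0)
        with pytest.raises(ValueError, match="occlusion_span"):
            ph.generate_phantom(spec)

    def test_every_branch_in_mask_and_centerlines(self, y_sample):
        labels = {b.label for b in ph.y_bifurcation_spec().branches}
        assert set(y_sample.mask.labels_present()) == labels
        assert {c.label for c in y_sample.centerlines} == labels


class TestAugment:
    def test_default_config_yields_six(self, noisy_sample):
        out = ph.augment(noisy_sample, ph.AugmentConfig(seed=0))
        assert len(out) == 6

    def test_flip_is_involution(self, noisy_sample):
        back = ph.flip_lr(ph.flip_lr(noisy_sample))
        for kind in SEQUENCE_KINDS:
            assert np.array_equal(back.volumes[kind].data,
                                  noisy_sample.volumes[kind].data)
        assert np.array_equal(back.mask.data, noisy_sample.mask.data)
        for a, b in zip(back.centerlines, noisy_sample.centerlines):
            assert np.allclose(a.points, b.points)
            assert a.side == b.side

    def test_flip_swaps_sides_conserves_labels(self):
        sample = ph.generate_phantom(ph.bilateral_spec(noise=0.0))
        flipped = ph.flip_lr(sample)
        assert sorted(c.label for c in flipped.centerlines) == \
            sorted(c.label for c in sample.centerlines)
        swap = {"left": "right", "right": "left", "midline": "midline"}
        for a, b in zip(sample.centerlines, flipped.centerlines):
            assert b.side == swap[a.side]

    def test_displacement_shifts_centerlines_exactly(self, noisy_sample):
        moved = ph.displace(noisy_sample, (5, 0, 0))
        dx = np.asarray(noisy_sample.spacing) * [5, 0, 0]
        for a, b in zip(noisy_sample.centerlines, moved.centerlines):
            assert np.allclose(b.points - a.points, dx)

    def test_displacement_pairs_image_and_mask(self, straight_sample):
        moved = ph.displace(straight_sample, (3, -2, 4))
        tof = moved.volumes["TOF"].data
        lum = ph.DEFAULT_LUMEN["TOF"]
        bg = ph.DEFAULT_BACKGROUND["TOF"]
        thresh = 0.5 * (lum + bg)
        assert np.array_equal(tof > thresh, moved.mask.data > 0)

    def test_geometry_appearance_consistency(self, straight_sample):
        # thresholding the noiseless TOF reproduces the transformed mask
        # voxel-for-voxel, excluding occluded spans
        lum = ph.DEFAULT_LUMEN["TOF"]
        bg = ph.DEFAULT_BACKGROUND["TOF"]
        thresh = 0.5 * (lum + bg)
        for s in ph.augment(straight_sample, ph.AugmentConfig(seed=4)):
            tof = s.volumes["TOF"].data
            relumen = tof > thresh
            expected = (s.mask.data > 0) & ~s.occluded
            assert np.array_equal(relumen, expected)

    def test_simulated_occlusion_only_touches_tof(self, straight_sample):
        rng = np.random.default_rng(2)
        occ = ph.simulate_occlusion(straight_sample, rng, 6.0)
        assert np.array_equal(occ.mask.data, straight_sample.mask.data)
        assert np.array_equal(occ.volumes["T1WI"].data,
                              straight_sample.volumes["T1WI"].data)
        changed = occ.volumes["TOF"].data != straight_sample.volumes["TOF"].data
        assert changed.any()
        assert (straight_sample.mask.data[changed] > 0).all()

    def test_truncation_keeps_vessel(self, noisy_sample):
        for seed in range(5):
            out = ph.augment(noisy_sample, ph.AugmentConfig(seed=seed))
            truncated = out[2]
            assert truncated.mask.data.any()
            assert truncated.mask.shape < noisy_sample.mask.shape
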