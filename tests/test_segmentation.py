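"""Network construction, training mechanics, channel logic and fusion."""

import numpy as np
import pytest

from angiorecon import phantoms as ph
from angiorecon.segmentation import (NetConfig, SegOutput, TrainConfig,
                                     build_model, dice_loss, dice_loss_grad,
                                     foreground_dice, fuse_segmentations,
                                     load_model, one_hot, prepare_channels,
                                     save_model, segment, train)
from angiorecon.segmentation.nn import softmax, softmax_backward
from angiorecon.types import LABEL_VALUES, Volume3D


def tiny_config(**kw):
    base = dict(in_channels=2, n_classes=3, base_width=2, n_scales=2, seed=1)
    base.update(kw)
    return NetConfig(**base)


def make_pair(seed, grid=16, n_classes=2):
    spec = ph.random_phantom_spec(seed, grid=grid, n_branches=1)
    sample = ph.generate_phantom(spec)
    prep = prepare_channels({k: v for k, v in sample.volumes.items()
                             if k != "TOF"})
    target = sample.mask.data.astype(np.int64)
    if n_classes == 2:
        target = (target > 0).astype(np.int64)
    return prep.black.array, target


class TestBuildModel:
    def test_shape_contract(self):
        model = build_model(tiny_config(n_classes=9))
        x = np.random.default_rng(0).normal(size=(2, 16, 16, 16)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (9, 16, 16, 16)

    def test_softmax_normalised(self):
        model = build_model(tiny_config())
        x = np.random.default_rng(1).normal(size=(2, 8, 8, 8)).astype(np.float32)
        p = softmax(model.forward(x))
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-5)
        assert (p >= 0).all()

    def test_indivisible_grid_rejected_by_forward(self):
        model = build_model(tiny_config())
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((2, 10, 8, 8), np.float32))

    def test_segment_pads_and_crops_odd_grids(self):
        model = build_model(tiny_config())
        from angiorecon.segmentation.ops import PreparedInput
        arr = np.random.default_rng(2).normal(size=(2, 10, 11, 9)).astype(np.float32)
        out = segment(model, PreparedInput(arr, (1, 1, 1), "T1WI"))
        assert out.mask.shape == (10, 11, 9)
        assert np.allclose(out.prob.sum(axis=0), 1.0, atol=1e-5)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(tiny_config())
        x = np.random.default_rng(3).normal(size=(2, 8, 8, 8)).astype(np.float32)
        y0 = model.forward(x)
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        clone = load_model(path)
        assert np.allclose(clone.forward(x), y0)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        model = build_model(tiny_config())
        x = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        t = rng.integers(0, 3, size=(8, 8, 8))
        oh = one_hot(t, 3)

        model.zero_grad()
        prob = softmax(model.forward(x))
        model.backward(softmax_backward(prob, dice_loss_grad(prob, oh)))

        params = model.params
        rs = np.random.default_rng(7)
        eps = 1e-3
        checked = 0
        for k in rs.choice(len(params), size=12, replace=False):
            p = params[k]
            idx = tuple(rs.integers(0, s) for s in p.value.shape)
            orig = float(p.value[idx])
            p.value[idx] = orig + eps
            lp = dice_loss(softmax(model.forward(x)), oh)
            p.value[idx] = orig - eps
            lm = dice_loss(softmax(model.forward(x)), oh)
            p.value[idx] = orig
            fd = (lp - lm) / (2 * eps)
            an = float(p.grad[idx])
            if abs(fd) < 1e-4 and abs(an) < 1e-4:
                continue            # below float32 finite-difference noise
            assert an == pytest.approx(fd, rel=0.05, abs=1e-4)
            checked += 1
        assert checked >= 3


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((4, 4, 4), np.int64)
        t[1:3, 1:3, 1:3] = 1
        oh = one_hot(t, 2)
        assert dice_loss(oh, oh) == pytest.approx(0.0, abs=1e-3)

    def test_complement_prediction_near_one(self):
        t = np.zeros((4, 4, 4), np.int64)
        t[:2] = 1
        oh = one_hot(t, 2)
        complement = oh[::-1].copy()
        assert dice_loss(complement, oh) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_half_probability(self):
        # target foreground fraction 1/2, uniform p=0.5:
        # soft dice = 2*(0.5*N/2) / (N/2 + N/2) = 0.5 -> loss 0.5
        t = np.zeros((4, 4, 4), np.int64)
        t[:2] = 1
        oh = one_hot(t, 2)
        prob = np.full_like(oh, 0.5)
        assert dice_loss(prob, oh) == pytest.approx(0.5, abs=1e-3)

    def test_empty_foreground_class_skipped(self):
        t = np.zeros((4, 4, 4), np.int64)
        t[0, 0, 0] = 2                       # class 1 absent, class 2 present
        oh = one_hot(t, 3)
        assert dice_loss(oh, oh) == pytest.approx(0.0, abs=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 4, 4, 4)), np.zeros((2, 4, 4, 5)))


class TestPrepareChannels:
    def volumes(self, kinds, shape=(16, 16, 16)):
        rng = np.random.default_rng(0)
        return {k: Volume3D(rng.normal(100, 10, shape).astype(np.float32),
                            (1, 1, 1), k) for k in kinds}

    def test_both_black_blood_sequences(self):
        prep = prepare_channels(self.volumes(["T1WI", "T1WI-CE"]))
        assert prep.black is not None
        assert prep.black.array.shape[0] == 2
        assert prep.black.reference_kind == "T1WI"
        assert not prep.black.duplicated

    def test_single_sequence_duplicated(self):
        prep = prepare_channels(self.volumes(["T1WI"]))
        assert prep.black.duplicated
        assert np.array_equal(prep.black.array[0], prep.black.array[1])

    def test_tof_only_selects_bright_path(self):
        prep = prepare_channels(self.volumes(["TOF"]))
        assert prep.black is None
        assert prep.bright is not None
        assert prep.bright.array.shape[0] == 1

    def test_differing_grids_resampled_to_first_channel(self):
        vols = self.volumes(["T1WI"])
        rng = np.random.default_rng(1)
        vols["T1WI-CE"] = Volume3D(rng.normal(100, 10, (8, 8, 8)).astype(np.float32),
                                   (2, 2, 2), "T1WI-CE")
        prep = prepare_channels(vols)
        assert prep.black.array.shape == (2, 16, 16, 16)
        assert prep.black.reference_kind == "T1WI"

    def test_no_usable_sequence_rejected(self):
        with pytest.raises(ValueError, match="no usable sequence"):
            prepare_channels({})

    def test_duplication_equivalence_through_model(self):
        # single-sequence path output equals the dual path fed two copies
        vols = self.volumes(["T1WI"])
        prep_single = prepare_channels(vols)
        model = build_model(tiny_config())
        y_single = model.forward(prep_single.black.array)
        dup = np.stack([prep_single.black.array[0]] * 2)
        assert np.array_equal(model.forward(dup), y_single)


class TestTrain:
    def test_zero_epochs_identity(self):
        model = build_model(tiny_config(in_channels=2, n_classes=2))
        before = model.get_state()
        data = [make_pair(0)]
        model, history = train(model, data, TrainConfig(epochs=0))
        assert history["train_loss"] == []
        for a, b in zip(before, model.get_state()):
            assert np.array_equal(a, b)

    def test_loss_decreases_over_early_epochs(self):
        data = [make_pair(i) for i in range(2)]
        model = build_model(NetConfig(in_channels=2, n_classes=2,
                                      base_width=2, n_scales=2, seed=0))
        model, history = train(model, data,
                               TrainConfig(epochs=20, lr=3e-3, lr_decay=0.995,
                                           seed=0))
        losses = history["train_loss"]
        assert losses[10] <= losses[0]
        assert losses[-1] <= losses[9]

    def test_nan_loss_aborts_with_diagnostic(self, monkeypatch):
        from angiorecon.segmentation import ops
        monkeypatch.setattr(ops, "dice_loss", lambda *a, **k: float("nan"))
        model = build_model(tiny_config(in_channels=2, n_classes=2))
        with pytest.raises(RuntimeError, match="NaN.*sample"):
            ops.train(model, [make_pair(0)], TrainConfig(epochs=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(tiny_config()), [], TrainConfig(epochs=1))

    def test_heldout_dice_improves_with_dataset_size(self):
        # surrogate for learning-capacity recovery: bigger phantom training
        # sets give better held-out Dice (1 inversion allowed across seeds)
        val = [make_pair(900 + i, grid=16) for i in range(2)]
        inversions = 0
        for seed in range(2):
            scores = []
            for n in (2, 6):
                data = [make_pair(100 * seed + i, grid=16) for i in range(n)]
                model = build_model(NetConfig(in_channels=2, n_classes=2,
                                              base_width=2, n_scales=2,
                                              seed=seed))
                model, hist = train(model, data,
                                    TrainConfig(epochs=6, lr=3e-3,
                                                lr_decay=0.99, seed=seed),
                                    val_dataset=val)
                scores.append(max(hist["val_dice"]))
            if scores[1] < scores[0]:
                inversions += 1
        assert inversions <= 1


class TestFusion:
    def seg(self, prob, spacing=(1, 1, 1)):
        return SegOutput(prob, prob.argmax(axis=0), spacing, "T1WI")

    def test_identical_inputs_idempotent(self):
        rng = np.random.default_rng(0)
        prob = softmax(rng.normal(size=(3, 4, 4, 4)).astype(np.float32))
        a = self.seg(prob)
        fused = fuse_segmentations(a, self.seg(prob.copy()))
        assert np.array_equal(fused.data, a.mask)

    def test_empty_bright_keeps_black(self):
        rng = np.random.default_rng(1)
        black_prob = softmax(rng.normal(size=(3, 4, 4, 4)).astype(np.float32) * 3)
        bright_prob = np.zeros((3, 4, 4, 4), np.float32)
        bright_prob[0] = 1.0                  # all background
        fused = fuse_segmentations(self.seg(black_prob), self.seg(bright_prob))
        assert np.array_equal(fused.data, self.seg(black_prob).mask)

    def test_conflicting_voxel_max_prob_wins(self):
        # black says ICA with 0.6, bright says ECA with 0.9 -> ECA
        n = len(LABEL_VALUES) + 1
        black = np.zeros((n, 3, 3, 3), np.float32)
        bright = np.zeros((n, 3, 3, 3), np.float32)
        black[0] = bright[0] = 1.0
        ica, eca = LABEL_VALUES["ICA"], LABEL_VALUES["ECA"]
        black[:, 1, 1, 1] = 0.0
        black[ica, 1, 1, 1] = 0.6
        black[0, 1, 1, 1] = 0.4
        bright[:, 1, 1, 1] = 0.0
        bright[eca, 1, 1, 1] = 0.9
        bright[0, 1, 1, 1] = 0.1
        fused = fuse_segmentations(self.seg(black), self.seg(bright))
        assert fused.data[1, 1, 1] == eca

    def test_occlusion_candidate_keeps_black_label(self):
        # black foreground where bright sees background survives fusion
        n = len(LABEL_VALUES) + 1
        black = np.zeros((n, 2, 2, 2), np.float32)
        bright = np.zeros((n, 2, 2, 2), np.float32)
        bright[0] = 0.95
        ica = LABEL_VALUES["ICA"]
        black[0] = 0.45
        black[ica] = 0.55
        fused = fuse_segmentations(self.seg(black), self.seg(bright))
        assert (fused.data == ica).all()

    def test_commutative(self):
        rng = np.random.default_rng(5)
        a = softmax(rng.normal(size=(4, 3, 3, 3)).astype(np.float32))
        b = softmax(rng.normal(size=(4, 3, 3, 3)).astype(np.float32))
        f1 = fuse_segmentations(self.seg(a), self.seg(b))
        f2 = fuse_segmentations(self.seg(b), self.seg(a))
        assert np.array_equal(f1.data, f2.data)

    def test_frame_mismatch_rejected(self):
        a = self.seg(np.ones((2, 4, 4, 4), np.float32) / 2)
        b = self.seg(np.ones((2, 5, 5, 5), np.float32) / 2)
        with pytest.raises(ValueError, match="frame mismatch"):
            fuse_segmentations(a, b)


class TestForegroundDice:
    def test_perfect_match(self):
        t = np.zeros((4, 4, 4), np.int64)
        t[1:3] = 1
        assert foreground_dice(t, t, 2) == 1.0

    def test_absent_classes_ignored(self):
        t = np.zeros((4, 4, 4), np.int64)
        t[0, 0, 0] = 3
        p = t.copy()
        assert foreground_dice(p, t, 9) == 1.0
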