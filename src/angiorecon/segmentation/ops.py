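"""Segmentation pipeline operations around the network.

Covers sequence-fallback channel preparation, the soft-Dice training
objective, the training loop (Adam, exponential learning-rate decay,
best-validation model selection), full-volume inference, and the fusion
of black-blood and bright-blood model outputs.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from ..types import BLACK_BLOOD, VesselMask, Volume3D
from .model import Model, NetConfig
from .nn import Adam, softmax, softmax_backward

__all__ = ["PreparedInput", "PreparedChannels", "SegOutput", "TrainConfig",
           "prepare_channels", "dice_loss", "dice_loss_grad", "train",
           "segment", "fuse_segmentations"]

DICE_EPS = 1e-5


@dataclass
class PreparedInput:
    """Model-ready normalised channels in the first channel's frame."""

    array: np.ndarray                    # (C, D, H, W) float32, z-scored
    spacing: tuple[float, float, float]
    reference_kind: str                  # sequence defining the spatial frame
    duplicated: bool = False             # single sequence copied to both channels


@dataclass
class PreparedChannels:
    """Which model paths are available for a given input set."""

    black: Optional[PreparedInput] = None
    bright: Optional[PreparedInput] = None


def _zscore(data: np.ndarray, body_threshold: Optional[float] = None
            ) -> np.ndarray:
    """Z-score normalisation; optionally restricted to a body mask.

    ``body_threshold`` is a fraction of the intensity range above the
    minimum; phantoms have no air background, so the default normalises
    over the full volume.
    """
    x = np.asarray(data, dtype=np.float32)
    if body_threshold is not None:
        lo, hi = float(x.min()), float(x.max())
        mask = x > lo + body_threshold * (hi - lo)
        ref = x[mask] if mask.any() else x
    else:
        ref = x
    mu = float(ref.mean())
    sd = float(ref.std())
    return (x - mu) / (sd if sd > 0 else 1.0)


def _resample_to(vol: Volume3D, reference: Volume3D) -> np.ndarray:
    """Resample ``vol`` onto the reference grid (world-aligned, trilinear)."""
    if vol.shape == reference.shape and vol.spacing == reference.spacing:
        return np.asarray(vol.data, dtype=np.float32)
    idx = np.indices(reference.shape, dtype=float)
    coords = [idx[a] * reference.spacing[a] / vol.spacing[a] for a in range(3)]
    out = map_coordinates(vol.data.astype(float), coords, order=1,
                          mode="nearest")
    return out.astype(np.float32)


def prepare_channels(available: dict[str, Volume3D],
                     body_threshold: Optional[float] = None
                     ) -> PreparedChannels:
    """Assemble model inputs from whatever sequences are present.

    Black-blood path: channel 1 = T1WI, channel 2 = T1WI-CE; with only
    one of the two present it is duplicated across both channels. The
    spatial frame is fixed to channel 1; a second sequence on a
    different grid is resampled onto it. Bright-blood path: TOF alone.
    With no usable sequence at all this is an error.
    """
    black_present = [k for k in BLACK_BLOOD if k in available]
    out = PreparedChannels()
    if black_present:
        first = available[black_present[0]]
        if len(black_present) == 2:
            second = available[black_present[1]]
            ch2 = _resample_to(second, first)
            duplicated = False
        else:
            ch2 = np.asarray(first.data, dtype=np.float32)
            duplicated = True
        arr = np.stack([_zscore(first.data, body_threshold),
                        _zscore(ch2, body_threshold)])
        out.black = PreparedInput(arr.astype(np.float32), first.spacing,
                                  first.kind, duplicated)
    if "TOF" in available:
        tof = available["TOF"]
        arr = _zscore(tof.data, body_threshold)[None]
        out.bright = PreparedInput(arr.astype(np.float32), tof.spacing, "TOF")
    if out.black is None and out.bright is None:
        raise ValueError("no usable sequence: need T1WI, T1WI-CE or TOF")
    return out


# ---------------------------------------------------------------------------
# Soft-Dice loss
# ---------------------------------------------------------------------------

def _class_sums(prob: np.ndarray, onehot: np.ndarray):
    axes = tuple(range(1, prob.ndim))
    inter = (prob * onehot).sum(axis=axes)
    denom = prob.sum(axis=axes) + onehot.sum(axis=axes) + DICE_EPS
    present = onehot.sum(axis=axes) > 0
    present[0] = False                      # background excluded
    return inter, denom, present


def dice_loss(prob: np.ndarray, onehot: np.ndarray) -> float:
    """1 - soft Dice, averaged over non-empty foreground classes.

    ``1 - 2*sum(p*g) / (sum(p) + sum(g) + eps)`` per class; classes with
    no target foreground are skipped (the epsilon guards the division).
    """
    if prob.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {onehot.shape}")
    inter, denom, present = _class_sums(prob, onehot)
    if not present.any():
        return 0.0
    dice_c = 2.0 * inter[present] / denom[present]
    return float(1.0 - dice_c.mean())


def dice_loss_grad(prob: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """d(dice_loss)/d(prob), same shape as ``prob``."""
    inter, denom, present = _class_sums(prob, onehot)
    grad = np.zeros_like(prob, dtype=np.float32)
    k = int(present.sum())
    if k == 0:
        return grad
    for c in np.flatnonzero(present):
        # d/dp of 2I/S with S = sum(p)+sum(g)+eps: (2g*S - 2I)/S^2
        grad[c] = -(2.0 * onehot[c] * denom[c] - 2.0 * inter[c]) / denom[c] ** 2 / k
    return grad


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes,) + mask.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = mask == c
    return out


def foreground_dice(pred_mask: np.ndarray, truth_mask: np.ndarray,
                    n_classes: int) -> float:
    """Mean hard Dice over the foreground classes present in the truth."""
    vals = []
    for c in range(1, n_classes):
        t = truth_mask == c
        if not t.any():
            continue
        p = pred_mask == c
        denom = p.sum() + t.sum()
        vals.append(2.0 * np.logical_and(p, t).sum() / denom if denom else 1.0)
    return float(np.mean(vals)) if vals else 1.0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Adam training schedule (momentum 0.9, lr 1e-3, exponential decay,
    weight decay 1e-5); the decay rate per epoch defaults to 0.97."""

    epochs: int = 50
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5
    lr_decay: float = 0.97
    seed: int = 0


def train(model: Model, dataset: list[tuple[np.ndarray, np.ndarray]],
          hyper: TrainConfig | None = None,
          val_dataset: Optional[list[tuple[np.ndarray, np.ndarray]]] = None
          ) -> tuple[Model, dict]:
    """Train on (input, label-mask) pairs; return best-validation model.

    Inputs are ``(C, D, H, W)`` arrays, targets integer class grids.
    History records per-epoch mean training loss, validation loss and
    validation foreground Dice. With no validation set the training
    loss selects the best state. Zero epochs returns the model
    unchanged with an empty history. A NaN loss aborts with a
    diagnostic naming the offending sample.
    """
    hyper = hyper or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "val_dice": []}
    if hyper.epochs == 0:
        return model, history
    n_classes = model.config.n_classes
    opt = Adam(model.params, lr=hyper.lr, beta1=hyper.beta1, beta2=hyper.beta2,
               weight_decay=hyper.weight_decay)
    rng = np.random.default_rng(hyper.seed)
    best_state = model.get_state()
    best_score = np.inf

    def evaluate(pairs):
        losses, dices = [], []
        for x, t in pairs:
            logits = model.forward(x)
            prob = softmax(logits)
            oh = one_hot(t, n_classes)
            losses.append(dice_loss(prob, oh))
            dices.append(foreground_dice(prob.argmax(axis=0), t, n_classes))
        return float(np.mean(losses)), float(np.mean(dices))

    for epoch in range(hyper.epochs):
        lr = hyper.lr * hyper.lr_decay ** epoch
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for idx in order:
            x, t = dataset[idx]
            opt.zero_grad()
            logits = model.forward(x)
            prob = softmax(logits)
            oh = one_hot(t, n_classes)
            loss = dice_loss(prob, oh)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, sample {idx}")
            dlogits = softmax_backward(prob, dice_loss_grad(prob, oh))
            model.backward(dlogits)
            opt.step(lr=lr)
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_dataset:
            val_loss, val_dice = evaluate(val_dataset)
            history["val_loss"].append(val_loss)
            history["val_dice"].append(val_dice)
            score = val_loss
        else:
            history["val_loss"].append(np.nan)
            history["val_dice"].append(np.nan)
            score = history["train_loss"][-1]
        if score < best_score:
            best_score = score
            best_state = model.get_state()
    model.set_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# Inference and fusion
# ---------------------------------------------------------------------------

@dataclass
class SegOutput:
    """Per-voxel class probabilities + argmax labels in the channel-1 frame."""

    prob: np.ndarray                     # (n_classes, D, H, W), sums to 1
    mask: np.ndarray                     # (D, H, W) argmax class indices
    spacing: tuple[float, float, float]
    channel_reference: str


def segment(model: Model, prepared: PreparedInput) -> SegOutput:
    """Run the network on a prepared input, padding to scale divisibility.

    The volume is zero-padded up to a multiple of ``2**n_scales`` and
    the output cropped back, so the result is always in the input frame.
    """
    x = prepared.array
    div = model.config.divisor
    shape = np.asarray(x.shape[1:])
    target = (np.ceil(shape / div) * div).astype(int)
    pad = target - shape
    if pad.any():
        x = np.pad(x, ((0, 0), (0, pad[0]), (0, pad[1]), (0, pad[2])))
    logits = model.forward(x)
    prob = softmax(logits)
    prob = prob[:, :shape[0], :shape[1], :shape[2]]
    return SegOutput(prob.astype(np.float32), prob.argmax(axis=0),
                     prepared.spacing, prepared.reference_kind)


def fuse_segmentations(black: SegOutput, bright: SegOutput) -> VesselMask:
    """Voxelwise fusion of the black-blood and bright-blood outputs.

    The fused label is the argmax over the per-class maximum of the two
    probability maps — except at occlusion-candidate voxels (foreground
    for the black-blood model, background for the bright-blood model),
    where the black-blood label wins outright: an occluded segment is
    invisible on TOF but must survive fusion. The rule is applied
    symmetrically for voxels only the bright-blood model saw, keeping
    the fusion commutative.
    """
    if black.prob.shape != bright.prob.shape:
        raise ValueError(f"frame mismatch: {black.prob.shape} vs "
                         f"{bright.prob.shape}; resample before fusing")
    if black.spacing != bright.spacing:
        raise ValueError(f"spacing mismatch: {black.spacing} vs {bright.spacing}")
    combined = np.maximum(black.prob, bright.prob)
    fused = combined.argmax(axis=0)
    only_black = (black.mask > 0) & (bright.mask == 0)
    fused[only_black] = black.mask[only_black]
    only_bright = (bright.mask > 0) & (black.mask == 0)
    fused[only_bright] = bright.mask[only_bright]
    return VesselMask(fused.astype(np.uint8), black.spacing)
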