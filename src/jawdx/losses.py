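"""The three training losses and mask dilation.

* ``classification_loss`` — mean negative log-likelihood of the true class
  (standard cross-entropy), L_CE.
* ``segmentation_loss`` — mean over samples of the squared Euclidean norm of
  the predicted-minus-true mask difference (sum over pixels), L_MSE; an
  optional per-pixel normalisation divides by the pixel count.
* ``consistency_loss`` — the Grad-CAM position constraint, L_constrain: for a
  lesion sample with dilated ground-truth mask M^d at feature resolution and
  rectified response R, the per-sample value is
  ``sum((1 - M^d) * R) - sum(M^d * R)``; minimising it pushes response mass
  out of the background and into the (dilated) lesion area.  Healthy samples
  are omitted from the batch mean.

The dilation uses a disk structuring element of radius ``d`` (all integer
offsets with dx^2 + dy^2 <= d^2); during training ``d`` is drawn uniformly
from an integer range per sample per step, applied at input resolution, and
reduced to feature resolution by block-max pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk

logger = logging.getLogger(__name__)

__all__ = [
    "LossBundle", "DilatedMask", "classification_loss", "segmentation_loss",
    "dilate_mask", "mask_to_feature_res", "consistency_loss",
    "batch_consistency_loss", "total_loss",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LossBundle:
    ce: float
    mse: float
    constrain: float
    weights: tuple  # (w_ce, w_mse, w_con)

    @property
    def total(self) -> float:
        w_ce, w_mse, w_con = self.weights
        return w_ce * self.ce + w_mse * self.mse + w_con * self.constrain


@dataclass(frozen=True)
class DilatedMask:
    values: np.ndarray
    radius: int


def classification_loss(probs: np.ndarray, labels) -> float:
    """Mean negative log-probability assigned to the true class."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs must be (K, n_classes) matching labels")
    if probs.shape[0] < 1:
        raise ValueError("need at least one sample")
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        logger.warning("true-class probability of 0 clamped to %.0e", _EPS)
        p_true = np.clip(p_true, _EPS, None)
    return float(np.mean(-np.log(p_true)))


def segmentation_loss(pred_masks: np.ndarray, true_masks: np.ndarray,
                      per_pixel: bool = False) -> float:
    """Mean squared-error segmentation loss.

    Per sample, the squared L2 norm of the mask difference is summed over
    pixels (the printed formula); ``per_pixel=True`` divides by the pixel
    count instead.
    """
    pred = np.asarray(pred_masks, dtype=np.float64)
    true = np.asarray(true_masks, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if pred.ndim == 2:
        pred, true = pred[None], true[None]
    k = pred.shape[0]
    per_sample = ((pred - true) ** 2).reshape(k, -1).sum(axis=1)
    if per_pixel:
        per_sample = per_sample / pred[0].size
    return float(per_sample.mean())


def dilate_mask(mask: np.ndarray, d: int) -> DilatedMask:
    """Morphological dilation with a disk structuring element of radius d."""
    if d < 0 or int(d) != d:
        raise ValueError("dilation radius must be a nonnegative integer")
    mask = np.asarray(mask) > 0
    if d == 0 or not mask.any():
        return DilatedMask(values=mask.astype(np.uint8), radius=int(d))
    out = dilation(mask, footprint=disk(int(d)))
    return DilatedMask(values=out.astype(np.uint8), radius=int(d))


def mask_to_feature_res(mask: np.ndarray, feature_shape: tuple) -> np.ndarray:
    """Reduce an input-resolution binary mask to feature resolution by
    block-max pooling (a feature cell is 'lesion' if any covered pixel is)."""
    fh, fw = feature_shape
    h, w = mask.shape
    if h % fh or w % fw:
        raise ValueError(f"mask {w}x{h} not divisible into {fw}x{fh} blocks")
    return mask.reshape(fh, h // fh, fw, w // fw).max(axis=(1, 3))


def consistency_loss(response: np.ndarray, dilated_mask: np.ndarray) -> float:
    """Position-consistency value for one lesion sample.

    ``sum((1 - M^d) * R) - sum(M^d * R)`` over the N feature cells.
    """
    r = np.asarray(response, dtype=np.float64)
    m = np.asarray(dilated_mask, dtype=np.float64)
    if r.shape != m.shape:
        raise ValueError(f"resolution mismatch: response {r.shape} vs "
                         f"mask {m.shape}")
    return float(((1.0 - m) * r).sum() - (m * r).sum())


def batch_consistency_loss(responses, dilated_masks, lesion_flags) -> float:
    """Mean of :func:`consistency_loss` over the lesion samples of a batch;
    healthy samples contribute nothing.  Returns 0 for an all-healthy batch."""
    vals = [consistency_loss(r, m)
            for r, m, is_lesion in zip(responses, dilated_masks, lesion_flags)
            if is_lesion]
    return float(np.mean(vals)) if vals else 0.0


def total_loss(ce: float, mse: float, constrain: float,
               weights=(1.0, 1.0, 1.0)) -> LossBundle:
    weights = tuple(float(w) for w in weights)
    if not all(np.isfinite(weights)):
        raise ValueError("loss weights must be finite")
    return LossBundle(ce=float(ce), mse=float(mse),
                      constrain=float(constrain), weights=weights)
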