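"""Preprocessing and the three lesion-aware augmentation strategies.

Preprocessing crops the common central area of each frame (the periphery of a
panoramic radiograph carries no lesions) and resizes to a fixed working
resolution, 512x256 at full scale.

Augmentations:

* horizontal flip;
* cut-and-paste — the lesion pixels of a lesion sample are pasted at the same
  coordinates onto a healthy frame, producing a new lesion sample;
* patch-covering — a lesion sample spawns ``patches_per_sample`` (default 20)
  occluded variants: half cover the whole lesion with a gray patch and are
  relabeled healthy with an emptied mask (a fully occluded lesion should be
  predicted healthy), half cover only healthy tissue and keep the original
  label and mask.  Patch sizes are drawn from the surveyed lesion-size range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from .data import LesionSizeStats, mask_bbox
from .phantoms import Sample

logger = logging.getLogger(__name__)

__all__ = ["AugmentConfig", "crop_and_resize", "horizontal_flip",
           "cut_and_paste", "patch_cover", "central_crop_box"]


@dataclass
class AugmentConfig:
    """Crop/resize and patch-covering parameters.

    ``crop_box`` is (x0, y0, x1, y1) half-open in source coordinates;
    ``target_size`` is (width, height).
    """

    crop_box: tuple
    target_size: tuple = (512, 256)
    patches_per_sample: int = 20
    patch_fill: float = 0.5       # mid-gray occluder
    max_placement_tries: int = 50

    def __post_init__(self):
        x0, y0, x1, y1 = self.crop_box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("degenerate crop_box")
        if min(self.target_size) <= 0:
            raise ValueError("target dimensions must be positive")
        if self.patches_per_sample % 2:
            raise ValueError("patches_per_sample must be even (half cover "
                             "the lesion, half cover healthy tissue)")
        if not 0.0 <= self.patch_fill <= 1.0:
            raise ValueError("patch_fill must be in [0, 1]")


def central_crop_box(height: int, width: int, frac_w: float = 0.8,
                     frac_h: float = 0.9) -> tuple:
    """Default crop: central 80% of width, 90% of height."""
    x0 = int(round(width * (1 - frac_w) / 2))
    y0 = int(round(height * (1 - frac_h) / 2))
    return (x0, y0, x0 + int(round(width * frac_w)),
            y0 + int(round(height * frac_h)))


def crop_and_resize(sample: Sample, config: AugmentConfig) -> Sample:
    """Crop to ``config.crop_box`` and resample to ``config.target_size``.

    The mask is interpolated then re-binarised at 0.5.  Cropping away lesion
    pixels is an error: lesions must survive preprocessing.
    """
    x0, y0, x1, y1 = config.crop_box
    h, w = sample.image.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"crop_box {config.crop_box} outside {w}x{h} frame")
    if sample.mask.any():
        bx0, by0, bx1, by1 = mask_bbox(sample.mask)
        if not (x0 <= bx0 and y0 <= by0 and bx1 <= x1 and by1 <= y1):
            raise ValueError(
                f"crop_box {config.crop_box} would clip lesion bbox "
                f"{(bx0, by0, bx1, by1)} of sample {sample.id!r}")
    tw, th = config.target_size
    img = sample.image[y0:y1, x0:x1]
    msk = sample.mask[y0:y1, x0:x1].astype(np.float64)
    if img.shape == (th, tw):
        out_img, out_msk = img.copy(), msk
    else:
        out_img = resize(img, (th, tw), order=1, anti_aliasing=False,
                         preserve_range=True)
        out_msk = resize(msk, (th, tw), order=1, anti_aliasing=False,
                         preserve_range=True)
    return replace(sample, image=out_img,
                   mask=(out_msk > 0.5).astype(np.uint8))


def horizontal_flip(sample: Sample) -> Sample:
    """Mirror image and mask about the vertical axis; label unchanged."""
    return replace(sample, image=sample.image[:, ::-1].copy(),
                   mask=sample.mask[:, ::-1].copy())


def cut_and_paste(lesion_sample: Sample, healthy_sample: Sample,
                  rng=None) -> Sample:
    """Paste the lesion pixels onto a healthy frame at the same coordinates."""
    if lesion_sample.category == "healthy":
        raise ValueError("cut_and_paste needs a lesion sample as source")
    if lesion_sample.image.shape != healthy_sample.image.shape:
        raise ValueError("cut_and_paste requires same-shaped samples")
    sel = lesion_sample.mask.astype(bool)
    img = healthy_sample.image.copy()
    img[sel] = lesion_sample.image[sel]
    return Sample(image=img, mask=lesion_sample.mask.copy(),
                  category=lesion_sample.category, split=lesion_sample.split,
                  id=f"{lesion_sample.id}+paste_{healthy_sample.id}")


def _apply_patch(sample: Sample, x0, y0, pw, ph, fill) -> np.ndarray:
    img = sample.image.copy()
    img[y0:y0 + ph, x0:x0 + pw] = fill
    return img


def patch_cover(lesion_sample: Sample, stats: LesionSizeStats,
                config: AugmentConfig, rng: np.random.Generator) -> list:
    """Generate the patch-covered variants of one lesion sample.

    Half the variants fully occlude the lesion bounding box (patch dims drawn
    between the sample's own bbox dims and the surveyed maxima) and are
    relabeled healthy with an empty mask; half occlude healthy tissue only
    (dims between the surveyed minima and maxima, zero mask overlap) and keep
    the label.  Variants whose patch cannot be placed within
    ``max_placement_tries`` are skipped with a warning.
    """
    if lesion_sample.category == "healthy":
        raise ValueError("patch_cover needs a lesion sample")
    h, w = lesion_sample.image.shape
    bx0, by0, bx1, by1 = mask_bbox(lesion_sample.mask)
    bw, bh = bx1 - bx0, by1 - by0
    half = config.patches_per_sample // 2
    empty = np.zeros_like(lesion_sample.mask)
    variants = []

    for i in range(half):  # lesion-covering: full occlusion, relabel healthy
        pw = int(rng.integers(bw, min(max(stats.max_w, bw), w) + 1))
        ph = int(rng.integers(bh, min(max(stats.max_h, bh), h) + 1))
        x_lo, x_hi = max(0, bx1 - pw), min(bx0, w - pw)
        y_lo, y_hi = max(0, by1 - ph), min(by0, h - ph)
        if x_lo > x_hi or y_lo > y_hi:  # patch cannot contain the bbox here
            logger.warning("patch_cover: no containing placement for %s "
                           "(variant %d)", lesion_sample.id, i)
            continue
        x0 = int(rng.integers(x_lo, x_hi + 1))
        y0 = int(rng.integers(y_lo, y_hi + 1))
        variants.append(Sample(
            image=_apply_patch(lesion_sample, x0, y0, pw, ph,
                               config.patch_fill),
            mask=empty.copy(), category="healthy", split=lesion_sample.split,
            id=f"{lesion_sample.id}+cover_lesion_{i}"))

    sel = lesion_sample.mask.astype(bool)
    for i in range(half):  # healthy-covering: zero overlap with the lesion
        pw = int(rng.integers(min(stats.min_w, w), min(stats.max_w, w) + 1))
        ph = int(rng.integers(min(stats.min_h, h), min(stats.max_h, h) + 1))
        placed = None
        for _ in range(config.max_placement_tries):
            x0 = int(rng.integers(0, w - pw + 1))
            y0 = int(rng.integers(0, h - ph + 1))
            if not sel[y0:y0 + ph, x0:x0 + pw].any():
                placed = (x0, y0)
                break
        if placed is None:
            logger.warning("patch_cover: no lesion-free placement for %s "
                           "(variant %d)", lesion_sample.id, i)
            continue
        variants.append(Sample(
            image=_apply_patch(lesion_sample, placed[0], placed[1], pw, ph,
                               config.patch_fill),
            mask=lesion_sample.mask.copy(), category=lesion_sample.category,
            split=lesion_sample.split,
            id=f"{lesion_sample.id}+cover_healthy_{i}"))
    return variants
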