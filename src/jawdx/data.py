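"""Dataset manifests, sample loading, and the lesion-size survey.

The manifest is a CSV with columns ``id, image_path, mask_path, category,
split`` (paths relative to the manifest's directory).  Masks are stored as
0/255 grayscale PNGs and binarised at > 127 on load.

The lesion-size survey measures tight mask bounding boxes over a set of
lesion samples; the resulting per-dimension min/max extents drive the sizing
of the occluding patches in the patch-covering augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantoms import CATEGORIES, SPLITS, Sample

__all__ = [
    "ManifestError", "ManifestRow", "DatasetManifest", "LesionSizeStats",
    "load_manifest", "load_sample", "load_samples",
    "mask_bbox", "survey_lesion_sizes",
]

MANIFEST_COLUMNS = ("id", "image_path", "mask_path", "category", "split")


class ManifestError(ValueError):
    """Structured manifest validation failure (names the offending row)."""


@dataclass(frozen=True)
class ManifestRow:
    id: str
    image_path: str
    mask_path: str
    category: str
    split: str


@dataclass
class DatasetManifest:
    rows: list
    root: Path

    @property
    def class_counts(self) -> dict:
        counts: dict = {}
        for row in self.rows:
            counts[row.category] = counts.get(row.category, 0) + 1
        return counts

    def split_counts(self) -> dict:
        counts: dict = {}
        for row in self.rows:
            key = (row.category, row.split)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def select(self, splits=None, categories=None) -> list:
        rows = self.rows
        if splits is not None:
            splits = {splits} if isinstance(splits, str) else set(splits)
            rows = [r for r in rows if r.split in splits]
        if categories is not None:
            categories = ({categories} if isinstance(categories, str)
                          else set(categories))
            rows = [r for r in rows if r.category in categories]
        return rows


def load_manifest(path, check_files: bool = True) -> DatasetManifest:
    """Read and validate a CSV manifest."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing columns {missing}")
    rows = []
    seen: set = set()
    root = path.parent
    for i, rec in enumerate(df.itertuples(index=False)):
        row = ManifestRow(rec.id, rec.image_path, rec.mask_path,
                          rec.category, rec.split)
        if row.id in seen:
            raise ManifestError(f"row {i}: duplicate id {row.id!r}")
        seen.add(row.id)
        if row.category not in CATEGORIES:
            raise ManifestError(
                f"row {i} (id={row.id!r}): unknown category {row.category!r};"
                f" expected one of {CATEGORIES}")
        if row.split not in SPLITS:
            raise ManifestError(
                f"row {i} (id={row.id!r}): unknown split {row.split!r};"
                f" expected one of {SPLITS}")
        if check_files:
            for p in (row.image_path, row.mask_path):
                if not (root / p).exists():
                    raise ManifestError(
                        f"row {i} (id={row.id!r}): missing file {p}")
        rows.append(row)
    return DatasetManifest(rows=rows, root=root)


def load_sample(row: ManifestRow, root) -> Sample:
    root = Path(root)
    image = np.asarray(iio.imread(root / row.image_path), dtype=np.float64)
    image /= 255.0
    mask = (np.asarray(iio.imread(root / row.mask_path)) > 127).astype(np.uint8)
    return Sample(image=image, mask=mask, category=row.category,
                  split=row.split, id=row.id)


def load_samples(manifest: DatasetManifest, splits=None,
                 categories=None) -> list:
    return [load_sample(row, manifest.root)
            for row in manifest.select(splits=splits, categories=categories)]


def mask_bbox(mask: np.ndarray) -> tuple:
    """Tight bounding box of a nonempty binary mask.

    Returns ``(x_min, y_min, x_max, y_max)``, 0-based and half-open, so
    ``width = x_max - x_min``.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("mask is empty; no bounding box")
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


@dataclass(frozen=True)
class LesionSizeStats:
    """Per-dimension min/max lesion bounding-box extents, in pixels."""

    min_w: int
    min_h: int
    max_w: int
    max_h: int

    def __post_init__(self):
        if not (0 < self.min_w <= self.max_w and 0 < self.min_h <= self.max_h):
            raise ValueError("invalid lesion size stats")


def survey_lesion_sizes(samples, split: str = "train",
                        all_splits: bool = False) -> LesionSizeStats:
    """Min/max lesion-bbox width and height over the selected lesion samples.

    By default only the training split is surveyed; ``all_splits=True``
    surveys every lesion sample regardless of split (which lets evaluation
    lesions influence the augmentation statistics — kept as an option, not
    the default).
    """
    widths, heights = [], []
    for s in samples:
        if s.category == "healthy":
            continue
        if not all_splits and s.split != split:
            continue
        x0, y0, x1, y1 = mask_bbox(s.mask)
        widths.append(x1 - x0)
        heights.append(y1 - y0)
    if not widths:
        raise ValueError("no lesion samples selected for the size survey")
    return LesionSizeStats(min_w=min(widths), min_h=min(heights),
                           max_w=max(widths), max_h=max(heights))


def survey_from_manifest(manifest: DatasetManifest, split: str = "train",
                         all_splits: bool = False) -> LesionSizeStats:
    rows = manifest.select(categories=list(c for c in CATEGORIES
                                           if c != "healthy"),
                           splits=None if all_splits else split)
    samples = [load_sample(r, manifest.root) for r in rows]
    return survey_lesion_sizes(samples, split=split, all_splits=True)
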