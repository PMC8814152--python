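"""Synthetic panoramic-radiograph phantoms with class-coded jaw lesions.

Real panoramic radiographs of jaw cysts and tumors are clinical data and not
redistributable, so this module fabricates grayscale frames that keep the
features the pipeline depends on: a bright central "jaw band" with smooth
texture, and darker (radiolucent) lesion regions whose morphology encodes the
diagnostic category —

* ``DC`` (dentigerous cyst): a single round-ish radiolucency attached to a
  bright crown-like disc, mimicking a cyst around an unerupted tooth crown.
* ``PC`` (periapical cyst): a small radiolucency at the apex of a bright
  root-like wedge.
* ``AB`` (ameloblastoma): a multilocular union of 2–4 overlapping lobes with a
  scalloped outline and near-isometric bounding box.
* ``KCOT`` (keratocystic odontogenic tumor): an elongated unilocular
  radiolucency with bounding-box aspect ratio >= 2 (anteroposterior spread).
* ``healthy``: no lesion, empty mask.

The mask is the exact support of the rendered radiolucency, lesions are darker
than their surroundings by at least 0.2 intensity, and everything is a pure
function of ``(category, seed, spec)`` so datasets are byte-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

CATEGORIES = ("DC", "PC", "AB", "KCOT", "healthy")
LESION_CATEGORIES = ("DC", "PC", "AB", "KCOT")
SPLITS = ("pretrain", "train", "val", "test")

__all__ = [
    "CATEGORIES", "LESION_CATEGORIES", "SPLITS",
    "Sample", "PhantomSpec", "render_phantom",
    "assign_splits", "generate_phantom_dataset",
]


@dataclass
class Sample:
    """One radiograph-like image with its lesion mask, label and split tag."""

    image: np.ndarray          # 2-D float in [0, 1]
    mask: np.ndarray           # 2-D uint8 in {0, 1}, same shape
    category: str              # one of CATEGORIES
    split: str                 # one of SPLITS
    id: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; "
                             f"expected one of {CATEGORIES}")
        if self.mask.shape != self.image.shape:
            raise ValueError("mask shape must match image shape")


@dataclass
class PhantomSpec:
    """Rendering and dataset-layout parameters for the phantom generator.

    ``lesion_size_range`` bounds the lesion bounding box per dimension, in
    pixels.  ``healthy_splits`` gives the (pretrain, val, test) counts for
    healthy frames; lesion classes are split 70/20/10 per class.
    """

    image_height: int = 128
    image_width: int = 256
    class_counts: dict = field(default_factory=lambda: {
        "DC": 20, "PC": 20, "AB": 20, "KCOT": 20})
    healthy_splits: tuple = (100, 20, 20)
    lesion_size_range: tuple = (12, 30)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        smin, smax = self.lesion_size_range
        if not (0 < smin <= smax):
            raise ValueError("lesion_size_range must satisfy 0 < min <= max")
        if min(self.image_height, self.image_width) < 4 * smax:
            raise ValueError("image dimensions must be at least 4x the "
                             "maximum lesion dimension")
        for cat, n in self.class_counts.items():
            if cat not in LESION_CATEGORIES:
                raise ValueError(f"unknown lesion category {cat!r}")
            if n < 0:
                raise ValueError("class counts must be >= 0")
        if any(n < 0 for n in self.healthy_splits):
            raise ValueError("healthy split counts must be >= 0")

    @staticmethod
    def tiny(seed: int = 0, **overrides) -> "PhantomSpec":
        """Desk-scale profile used by the fast tests (96x48 frames)."""
        spec = PhantomSpec(image_height=48, image_width=96,
                           class_counts={"DC": 8, "PC": 8, "AB": 8, "KCOT": 8},
                           healthy_splits=(40, 8, 8),
                           lesion_size_range=(6, 12), seed=seed)
        return replace(spec, **overrides) if overrides else spec


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.ogrid[:h, :w]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _disc_mask(h, w, cy, cx, r):
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _mask_bbox(mask):
    ys, xs = np.nonzero(mask)
    return xs.min(), ys.min(), xs.max() + 1, ys.max() + 1  # half-open


def _place_center(rng, spec, w, h):
    """Lesion-bbox center keeping the lesion inside the central 70% x 80%,
    so the default preprocessing crop can never clip lesion pixels."""
    W, H = spec.image_width, spec.image_height
    x_lo = int(np.ceil(0.15 * W + w / 2)) + 1
    x_hi = int(np.floor(0.85 * W - w / 2)) - 1
    y_lo = int(np.ceil(0.10 * H + h / 2)) + 1
    y_hi = int(np.floor(0.90 * H - h / 2)) - 1
    return (int(rng.integers(y_lo, max(y_lo, y_hi) + 1)),
            int(rng.integers(x_lo, max(x_lo, x_hi) + 1)))


def _lesion_geometry(category, rng, spec):
    """Return (mask, bright_overlay) where mask is the exact lesion support
    and bright_overlay marks crown/root structures drawn brighter."""
    H, W = spec.image_height, spec.image_width
    smin, smax = spec.lesion_size_range
    bright = np.zeros((H, W), dtype=bool)

    if category == "DC":
        rx = rng.uniform(smin / 2, (smax - 1) / 2)
        ry = float(np.clip(rx * rng.uniform(0.75, 1.3),
                           smin / 2.5, (smax - 1) / 2))
        cy, cx = _place_center(rng, spec, 2 * rx + 1, 2 * ry + 1)
        mask = _ellipse_mask(H, W, cy, cx, ry, rx)
        # bright crown-like disc attached to the top rim of the cyst
        bright = _disc_mask(H, W, cy - ry, cx, max(2.0, 0.35 * ry))
    elif category == "PC":
        r_hi = (smin + (smax - smin) / 3) / 2
        rx = rng.uniform(smin / 2, r_hi)
        ry = rng.uniform(smin / 2, r_hi)
        cy, cx = _place_center(rng, spec, 2 * rx + 1, 2 * ry + 1)
        mask = _ellipse_mask(H, W, cy, cx, ry, rx)
        # bright root-like wedge narrowing down to the apex at the lesion
        apex_y = cy - ry + 1
        root_h = max(3, int(1.8 * ry))
        yy, xx = np.ogrid[:H, :W]
        half_w = np.clip((apex_y - yy + root_h) / root_h, 0, 1) * max(1.5, rx)
        bright = (yy < apex_y) & (yy >= apex_y - root_h) & \
                 (np.abs(xx - cx) <= half_w)
    elif category == "AB":
        for _ in range(40):
            wb = rng.uniform(0.75 * smax, smax - 1)
            hb = rng.uniform(0.70 * wb, 0.95 * wb)
            hb = min(hb, smax - 1)
            cy, cx = _place_center(rng, spec, wb, hb)
            k = int(rng.integers(2, 5))
            mask = np.zeros((H, W), dtype=bool)
            for i in range(k):
                dx = rng.uniform(-0.22, 0.22) * wb
                dy = rng.uniform(-0.22, 0.22) * hb
                rx_i = rng.uniform(0.26, 0.40) * wb
                ry_i = rng.uniform(0.26, 0.40) * hb
                rx_i = min(rx_i, wb / 2 - abs(dx) - 0.5)
                ry_i = min(ry_i, hb / 2 - abs(dy) - 0.5)
                if rx_i < 1.5 or ry_i < 1.5:
                    continue
                mask |= _ellipse_mask(H, W, cy + dy, cx + dx, ry_i, rx_i)
            if not mask.any():
                continue
            x0, y0, x1, y1 = _mask_bbox(mask)
            aspect = (x1 - x0) / (y1 - y0)
            if 0.55 <= aspect <= 1.85 and min(x1 - x0, y1 - y0) >= smin - 1:
                break
        else:  # pragma: no cover - rejection loop practically always succeeds
            raise RuntimeError("failed to render a multilocular AB lesion")
    elif category == "KCOT":
        # floor(rx) >= 2*floor(ry) + 1 guarantees pixel bbox aspect >= 2
        ry_floor_max = max(1, (smax - 3) // 4)
        ry = rng.uniform(1.0, ry_floor_max + 0.99)
        rx = 2 * int(ry) + 1 + rng.uniform(0.0, 0.99)
        cy, cx = _place_center(rng, spec, 2 * rx + 1, 2 * ry + 1)
        mask = _ellipse_mask(H, W, cy, cx, ry, rx)
    else:
        raise ValueError(f"unknown category {category!r}; "
                         f"expected one of {CATEGORIES}")
    return mask, bright


def render_phantom(category: str, rng: np.random.Generator,
                   spec: PhantomSpec, sample_id: str = "",
                   split: str = "train") -> Sample:
    """Render one phantom radiograph of the given category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; "
                         f"expected one of {CATEGORIES}")
    H, W = spec.image_height, spec.image_width
    yy = np.linspace(0.0, 1.0, H)[:, None]
    xx = np.linspace(0.0, 1.0, W)[None, :]
    # curved jaw band: per-image centre height, curvature and thickness
    band_center = 0.5 + rng.uniform(-0.06, 0.06) + \
        rng.uniform(-0.25, 0.05) * (xx - 0.5) ** 2
    band_sigma = rng.uniform(0.16, 0.28)
    band = np.exp(-(((yy - band_center) / band_sigma) ** 2))
    img = 0.35 + 0.40 * band
    # slow per-image intensity field: acquisition tilt plus 2-3 broad
    # bone-density patches (low-frequency anatomy that identifies a frame)
    img = img + rng.uniform(-0.08, 0.08) * (xx - 0.5) + \
        rng.uniform(-0.06, 0.06) * (yy - 0.5)
    for _ in range(int(rng.integers(2, 4))):
        py, px = rng.uniform(0.2, 0.8) * H, rng.uniform(0.1, 0.9) * W
        sig = rng.uniform(0.12, 0.30) * H
        amp = rng.uniform(-0.09, 0.09)
        img = img + amp * np.exp(-(((yy * H - py) ** 2 +
                                    (xx * W - px) ** 2) / (2 * sig ** 2)))
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(H, W)), sigma=3.0)
    img = img + 0.05 * texture + rng.uniform(-0.04, 0.04)
    # dental arches: two rows of bright tooth-like blocks along the band.
    # Tooth count, pitch, widths, row gap and heights are drawn per image,
    # giving each frame a structural identity (as patient anatomy does)
    # that survives brightness changes and modest crops.
    n_teeth = int(rng.integers(max(4, W // 16), max(6, W // 6)))
    pitch = W / n_teeth
    width_factor = rng.uniform(0.30, 0.60)
    row_gap = rng.uniform(0.04, 0.12) * H
    tooth_h = rng.uniform(0.18, 0.30) * H
    ys, xs = np.ogrid[:H, :W]
    for t in range(n_teeth):
        cx = (t + 0.5) * pitch + rng.uniform(-0.2, 0.2) * pitch
        tw = width_factor * pitch * rng.uniform(0.8, 1.2)
        cy0 = float(np.interp(cx / W, xx[0], band_center[0])) * H
        gain = rng.uniform(0.10, 0.22)
        for sign in (-1, 1):  # upper and lower arch
            th = tooth_h * rng.uniform(0.6, 1.0)
            cy = cy0 + sign * (row_gap / 2 + th / 2)
            tooth = (np.abs(xs - cx) <= tw / 2) & (np.abs(ys - cy) <= th / 2)
            img[tooth] += gain

    if category == "healthy":
        mask = np.zeros((H, W), dtype=np.uint8)
    else:
        lesion, bright = _lesion_geometry(category, rng, spec)
        base = img.copy()
        img[bright] += 0.22
        # radiolucency: darker than the pre-overlay background by >= 0.25
        depth = rng.uniform(0.25, 0.35)
        img[lesion] = base[lesion] - depth
        mask = lesion.astype(np.uint8)

    img = img + rng.normal(0.0, spec.noise_sd, size=(H, W))
    img = np.clip(img, 0.02, 0.98)
    return Sample(image=img, mask=mask, category=category,
                  split=split, id=sample_id or f"{category}_0")


def _sample_rng(spec: PhantomSpec, category: str, index: int):
    cat_idx = CATEGORIES.index(category)
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, cat_idx, index]))


def assign_splits(spec: PhantomSpec) -> list[tuple[str, str, str]]:
    """Deterministic (id, category, split) plan for a spec.

    Lesion classes: floor(0.7 n) train, floor(0.2 n) val, remainder test, in
    id order.  Healthy frames take the explicit (pretrain, val, test) counts.
    """
    plan = []
    for cat in LESION_CATEGORIES:
        n = spec.class_counts.get(cat, 0)
        n_train, n_val = int(0.7 * n), int(0.2 * n)
        for i in range(n):
            split = ("train" if i < n_train
                     else "val" if i < n_train + n_val else "test")
            plan.append((f"{cat}_{i:05d}", cat, split))
    n_pre, n_val, n_test = spec.healthy_splits
    for i in range(n_pre + n_val + n_test):
        split = ("pretrain" if i < n_pre
                 else "val" if i < n_pre + n_val else "test")
        plan.append((f"healthy_{i:05d}", "healthy", split))
    return plan


def render_dataset(spec: PhantomSpec) -> list[Sample]:
    """Render every sample in the split plan, in memory."""
    samples = []
    for sample_id, cat, split in assign_splits(spec):
        idx = int(sample_id.rsplit("_", 1)[1])
        rng = _sample_rng(spec, cat, idx)
        samples.append(render_phantom(cat, rng, spec, sample_id, split))
    return samples


def generate_phantom_dataset(spec: PhantomSpec, out_dir) -> Path:
    """Write images, masks and a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample_id, cat, split in assign_splits(spec):
        idx = int(sample_id.rsplit("_", 1)[1])
        rng = _sample_rng(spec, cat, idx)
        sample = render_phantom(cat, rng, spec, sample_id, split)
        image_path = f"images/{sample_id}.png"
        mask_path = f"masks/{sample_id}.png"
        iio.imwrite(out_dir / image_path,
                    np.round(sample.image * 255).astype(np.uint8))
        iio.imwrite(out_dir / mask_path, sample.mask * np.uint8(255))
        rows.append((sample_id, image_path, mask_path, cat, split))
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "mask_path", "category", "split"])
        writer.writerows(rows)
    return manifest_path
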