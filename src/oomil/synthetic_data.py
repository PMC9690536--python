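"""Synthetic mammogram-like images with ordinal multi-instance ground truth.

Each generated image is a "bag": a tall grayscale frame of noisy tissue-like
texture with a dark border, containing zero or more lesion blobs.  Blob
grades follow the ordinal MIL contract: every blob grade is <= the bag
label, and at least one blob carries exactly the bag label, so the maximum
instance grade equals the bag grade.  Grade-1 (benign-like) blobs are smooth
isotropic bright spots; grade-2 (cancer-like) blobs are brighter and carry a
spiculated, irregular boundary.  Per-cell instance labels are defined on the
same 14x7 grid the bag builder uses: a cell's label is the maximum grade of
any blob whose support overlaps it.

Nothing here aims at radiographic realism; the generator reproduces the
*statistical* structure the learning method assumes (ordered appearance of
grades, bag-label semantics, background clutter, dark borders that exercise
threshold filtering).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

CLASSES = (0, 1, 2)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_image",
    "generate_dataset",
    "make_instance_test_set",
    "save_instance_test_set",
    "load_instance_test_set",
    "grid_cell_labels",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic bag generator.

    Defaults give an "easy" high-contrast regime: grade-2 blobs clearly
    brighter than grade-1 blobs, which are clearly brighter than background,
    while background noise keeps single pixels uninformative.
    """

    image_height: int = 448
    image_width: int = 224
    n_bags_per_class: int = 10
    background_mean: float = 0.25
    background_sd: float = 0.05
    border_margin: int = 32
    lesion_intensity: dict = field(default_factory=lambda: {1: 0.60, 2: 0.90})
    lesion_radius: float = 13.0
    n_lesions_range: tuple = (1, 3)
    irregularity: float = 0.35
    grid_rows: int = 14
    grid_cols: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.image_height % self.grid_rows != 0 or self.image_width % self.grid_cols != 0:
            raise ValueError(
                f"image {self.image_height}x{self.image_width} not divisible by "
                f"grid {self.grid_rows}x{self.grid_cols}"
            )
        if not (self.lesion_intensity[2] > self.lesion_intensity[1] > self.background_mean):
            raise ValueError("lesion intensities must be ordered: grade2 > grade1 > background")
        if not (0.0 <= self.background_mean <= 1.0):
            raise ValueError("background_mean must lie in [0, 1]")
        lo, hi = self.n_lesions_range
        if lo < 1 or hi < lo:
            raise ValueError("n_lesions_range must satisfy 1 <= min <= max")

    @property
    def cell_shape(self) -> tuple:
        return self.image_height // self.grid_rows, self.image_width // self.grid_cols


@dataclass
class GroundTruth:
    """Bag label plus the hidden per-cell instance labels (row-major grid)."""

    bag_label: int
    instance_labels: list

    def validate(self) -> None:
        if self.instance_labels:
            if max(self.instance_labels) != self.bag_label:
                raise ValueError("max instance label must equal the bag label")
            if any(lab > self.bag_label for lab in self.instance_labels):
                raise ValueError("instance labels may not exceed the bag label")


@dataclass
class _Lesion:
    row: float
    col: float
    grade: int
    radius: float
    # spiculation parameters; amplitude 0 -> smooth isotropic blob
    amp: float = 0.0
    n_spicules: int = 0
    phase: float = 0.0

    def mask_and_profile(self, shape: tuple) -> tuple:
        """Boolean support mask and additive intensity profile on `shape`."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        dy = yy - self.row
        dx = xx - self.col
        dist = np.hypot(dy, dx)
        if self.amp > 0 and self.n_spicules > 0:
            theta = np.arctan2(dy, dx)
            wobble = 0.6 * np.cos(self.n_spicules * theta + self.phase) + 0.4 * np.cos(
                (self.n_spicules + 3) * theta + 2.1 * self.phase
            )
            r_eff = self.radius * np.clip(1.0 + self.amp * wobble, 0.3, None)
        else:
            r_eff = np.full(shape, self.radius)
        mask = dist <= r_eff
        # smooth radial falloff; ~0.22 of peak at the support boundary
        profile = np.exp(-1.5 * (dist / np.maximum(r_eff, 1e-9)) ** 2)
        profile[~mask] = 0.0
        return mask, profile


def grid_cell_labels(
    masks: Sequence[np.ndarray],
    grades: Sequence[int],
    grid_rows: int,
    grid_cols: int,
) -> list:
    """Label each grid cell with the max grade of overlapping lesion supports.

    A cell counts as overlapped as soon as one pixel of a lesion's support
    mask falls inside it ("strongest label" semantics).
    """
    if not masks:
        return [0] * (grid_rows * grid_cols)
    h, w = masks[0].shape
    ch, cw = h // grid_rows, w // grid_cols
    labels = np.zeros((grid_rows, grid_cols), dtype=int)
    for mask, grade in zip(masks, grades):
        for r in range(grid_rows):
            for c in range(grid_cols):
                if labels[r, c] < grade and mask[r * ch : (r + 1) * ch, c * cw : (c + 1) * cw].any():
                    labels[r, c] = grade
    return labels.ravel().tolist()


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    noise = rng.standard_normal((h, w))
    texture = ndimage.gaussian_filter(noise, sigma=2.5)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    img = cfg.background_mean + cfg.background_sd * texture
    m = cfg.border_margin
    if m > 0:
        border = np.zeros((h, w), dtype=bool)
        border[:m, :] = border[-m:, :] = True
        border[:, :m] = border[:, -m:] = True
        img[border] = 0.01 + 0.01 * np.abs(noise[border]) * 0.5
    return img


def _sample_lesions(cfg: SynthConfig, bag_label: int, rng: np.random.Generator) -> list:
    """Lesion blobs for one image, anchored to distinct interior grid cells.

    Each lesion sits near the centre of its own cell (small jitter), so a
    positive bag contains one clearly lesion-bearing instance per blob --
    the discrete structure the bag-of-patches decomposition assumes.  The
    first lesion is forced to the bag grade; the rest may be milder.
    """
    lo, hi = cfg.n_lesions_range
    interior = _interior_cells(cfg)
    if not interior:
        raise ValueError("no interior cells available for lesion placement")
    n = min(int(rng.integers(lo, hi + 1)), len(interior))
    picks = rng.choice(len(interior), size=n, replace=False)
    # extra lesions repeat the bag grade more often than not, so a positive
    # bag carries several instances of its own grade (the key instances)
    grades = [bag_label] + [
        bag_label if rng.random() < 0.7 else int(rng.integers(1, bag_label + 1))
        for _ in range(n - 1)
    ]
    ch, cw = cfg.cell_shape
    jitter = min(ch, cw) / 6.0
    lesions = []
    for pick, g in zip(picks, grades):
        r, c = interior[pick]
        row = (r + 0.5) * ch + float(rng.uniform(-jitter, jitter))
        col = (c + 0.5) * cw + float(rng.uniform(-jitter, jitter))
        radius = float(cfg.lesion_radius * rng.uniform(0.85, 1.15))
        if g == 2:
            les = _Lesion(
                row,
                col,
                g,
                radius,
                amp=cfg.irregularity,
                n_spicules=int(rng.integers(5, 10)),
                phase=float(rng.uniform(0, 2 * math.pi)),
            )
        else:
            les = _Lesion(row, col, g, radius)
        lesions.append(les)
    return lesions


def _render(cfg: SynthConfig, bag_label: int, rng: np.random.Generator, lesions=None):
    img = _background(cfg, rng)
    if lesions is None:
        lesions = _sample_lesions(cfg, bag_label, rng) if bag_label > 0 else []
    masks = []
    for les in lesions:
        mask, profile = les.mask_and_profile(img.shape)
        contrast = cfg.lesion_intensity[les.grade] - cfg.background_mean
        lifted = np.maximum(img, cfg.background_mean + contrast * profile)
        img = np.where(profile > 0, lifted, img)
        masks.append(mask)
    labels = grid_cell_labels(masks, [l.grade for l in lesions], cfg.grid_rows, cfg.grid_cols)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return img, GroundTruth(bag_label=bag_label, instance_labels=labels), lesions


def generate_image(
    cfg: SynthConfig,
    bag_label: int,
    rng: Optional[np.random.Generator] = None,
):
    """Generate one image and its ground truth for the given bag label.

    Returns ``(image, GroundTruth)`` where image is float32 in [0, 1] of
    shape ``(image_height, image_width)``.  For ``bag_label == 0`` the image
    contains no lesion and every cell label is 0; otherwise at least one blob
    carries exactly the bag grade and no blob exceeds it.
    """
    cfg.validate()
    if bag_label not in CLASSES:
        raise ValueError(f"bag_label must be one of {CLASSES}, got {bag_label!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    img, gt, _ = _render(cfg, bag_label, rng)
    gt.validate()
    return img, gt


def _bag_rng(cfg: SynthConfig, *stream: int) -> np.random.Generator:
    # counter-based substream: reproducible regardless of generation order
    return np.random.default_rng([cfg.seed, *stream])


def generate_dataset(cfg: SynthConfig, out_dir: Optional[str] = None):
    """Generate ``n_bags_per_class`` images for each of the three classes.

    Returns a list of ``(bag_id, image, GroundTruth)`` triples, stratified
    and deterministic under ``cfg.seed``.  If ``out_dir`` is given, images
    are written as 8-bit grayscale PNGs plus a JSON-lines ground-truth
    manifest (``manifest.jsonl``) with one record per bag.
    """
    cfg.validate()
    if cfg.n_bags_per_class < 1:
        raise ValueError("n_bags_per_class must be >= 1")
    records = []
    for label in CLASSES:
        for i in range(cfg.n_bags_per_class):
            rng = _bag_rng(cfg, label, i)
            img, gt, _ = _render(cfg, label, rng)
            gt.validate()
            records.append((f"c{label}_{i:04d}", img, gt))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_lines = []
        for bag_id, img, gt in records:
            fname = f"{bag_id}.png"
            iio.imwrite(out / fname, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))
            manifest_lines.append(
                json.dumps(
                    {
                        "bag_id": bag_id,
                        "image_path": fname,
                        "bag_label": gt.bag_label,
                        "instance_labels": gt.instance_labels,
                    },
                    sort_keys=True,
                )
            )
        (out / "manifest.jsonl").write_text("\n".join(manifest_lines) + "\n")
    return records


def _interior_cells(cfg: SynthConfig) -> list:
    """Grid cells fully inside the non-border region."""
    ch, cw = cfg.cell_shape
    m = cfg.border_margin
    cells = []
    for r in range(cfg.grid_rows):
        for c in range(cfg.grid_cols):
            if r * ch >= m and (r + 1) * ch <= cfg.image_height - m and c * cw >= m and (c + 1) * cw <= cfg.image_width - m:
                cells.append((r, c))
    return cells


def make_instance_test_set(cfg: SynthConfig, n_per_class: int, patch_side: int = 224):
    """Labeled single patches for instance-level evaluation.

    Class-1/2 patches are cut at lesion centers (the region of interest of a
    diseased image); class-0 patches come from lesion-free interior tissue.
    Each patch is resized to ``patch_side`` x ``patch_side``, matching the
    instances the network is trained on.  Returns a list of
    ``(patch, class_index)`` pairs, ``3 * n_per_class`` in total.
    """
    cfg.validate()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ch, cw = cfg.cell_shape
    interior = _interior_cells(cfg)
    out = []
    for label in CLASSES:
        for i in range(n_per_class):
            rng = _bag_rng(cfg, 1000 + label, i)
            r, c = interior[int(rng.integers(len(interior)))]
            if label == 0:
                img, gt, _ = _render(cfg, label, rng)
            else:
                # region of interest: one lesion of the target grade placed at
                # the centre of a grid cell, so the cropped cell is a clean,
                # in-distribution example of that grade
                row, col = (r + 0.5) * ch, (c + 0.5) * cw
                radius = float(cfg.lesion_radius * rng.uniform(0.85, 1.15))
                if label == 2:
                    les = _Lesion(
                        row, col, 2, radius,
                        amp=cfg.irregularity,
                        n_spicules=int(rng.integers(5, 10)),
                        phase=float(rng.uniform(0, 2 * math.pi)),
                    )
                else:
                    les = _Lesion(row, col, 1, radius)
                img, gt, _ = _render(cfg, label, rng, lesions=[les])
                assert gt.instance_labels[r * cfg.grid_cols + c] == label
            patch = img[r * ch : (r + 1) * ch, c * cw : (c + 1) * cw]
            patch = _sk_resize(
                patch, (patch_side, patch_side), order=1, anti_aliasing=False, preserve_range=True
            )
            out.append((np.clip(patch, 0.0, 1.0).astype(np.float32), label))
    return out


def save_instance_test_set(test_set, out_dir: str) -> None:
    """Write labeled patches as PNGs plus a labels.jsonl manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, (patch, label) in enumerate(test_set):
        fname = f"patch_{i:04d}_y{label}.png"
        iio.imwrite(out / fname, (np.clip(patch, 0, 1) * 255).round().astype(np.uint8))
        lines.append(json.dumps({"patch_path": fname, "label": int(label)}))
    (out / "labels.jsonl").write_text("\n".join(lines) + "\n")


def load_instance_test_set(in_dir: str):
    """Read a labeled patch set written by :func:`save_instance_test_set`."""
    root = Path(in_dir)
    out = []
    for line in (root / "labels.jsonl").read_text().splitlines():
        rec = json.loads(line)
        patch = iio.imread(root / rec["patch_path"]).astype(np.float32) / 255.0
        out.append((patch, int(rec["label"])))
    return out
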