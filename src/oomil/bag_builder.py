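"""Turn a whole image into a bag of fixed-size instances.

Pipeline: grid patching (14 rows x 7 columns by default, 98 patches) ->
threshold filtering of background/noise patches -> balancing to a fixed bag
size (70) by flip/rotate augmentation or foreground-ranked trimming ->
bilinear resize of every instance to 224 x 224.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Instance",
    "Bag",
    "BagBuildConfig",
    "EmptyBagError",
    "grid_patch",
    "threshold_filter",
    "balance_bag",
    "finalize",
    "build_bag",
    "save_bags",
    "load_bags",
    "AUGMENTATIONS",
]


class EmptyBagError(ValueError):
    """Raised when threshold filtering removes every patch of a bag."""


@dataclass
class Instance:
    """One patch of a bag: pixels plus its grid position and provenance."""

    pixels: np.ndarray
    grid_row: int
    grid_col: int
    augmentation_tag: str = "none"
    hidden_label: Optional[int] = None  # ground truth for evaluation only

    @property
    def foreground_fraction(self) -> float:
        # fraction of pixels above the *default* threshold; recomputed with
        # the configured threshold where it matters (filtering/trimming)
        return float(np.mean(self.pixels > 0.08))


@dataclass
class Bag:
    bag_id: str
    instances: List[Instance]
    label: int


@dataclass
class BagBuildConfig:
    grid_rows: int = 14
    grid_cols: int = 7
    foreground_threshold: float = 0.08
    min_foreground_fraction: float = 0.25
    target_bag_size: int = 70
    patch_side: int = 224
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.foreground_threshold <= 1.0 and 0.0 <= self.min_foreground_fraction <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.grid_rows < 1 or self.grid_cols < 1 or self.target_bag_size < 1:
            raise ValueError("grid shape and target bag size must be positive")


# ordered transform list used to fill undersized bags; composed transforms
# extend the basic flips/rotations so arbitrarily large deficits can be met
AUGMENTATIONS = (
    "hflip",
    "vflip",
    "rot90",
    "rot180",
    "rot270",
    "hflip+rot90",
    "hflip+rot180",
    "hflip+rot270",
)


def _apply_augmentation(pixels: np.ndarray, tag: str) -> np.ndarray:
    out = pixels
    for part in tag.split("+"):
        if part == "none":
            continue
        elif part == "hflip":
            out = out[:, ::-1]
        elif part == "vflip":
            out = out[::-1, :]
        elif part == "rot90":
            out = np.rot90(out, 1)
        elif part == "rot180":
            out = np.rot90(out, 2)
        elif part == "rot270":
            out = np.rot90(out, 3)
        else:
            raise ValueError(f"unknown augmentation {part!r}")
    return np.ascontiguousarray(out)


def grid_patch(image: np.ndarray, grid_rows: int = 14, grid_cols: int = 7) -> List[Instance]:
    """Split an image into a row-major list of non-overlapping grid patches.

    If the image dimensions are not divisible by the grid, it is first
    center-cropped to the largest divisible size.
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    h, w = image.shape
    ph, pw = h // grid_rows, w // grid_cols
    if ph == 0 or pw == 0:
        raise ValueError(f"image {h}x{w} too small for a {grid_rows}x{grid_cols} grid")
    oh, ow = (h - ph * grid_rows) // 2, (w - pw * grid_cols) // 2
    cropped = image[oh : oh + ph * grid_rows, ow : ow + pw * grid_cols]
    patches = []
    for r in range(grid_rows):
        for c in range(grid_cols):
            pix = np.array(cropped[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw], dtype=np.float32)
            patches.append(Instance(pixels=pix, grid_row=r, grid_col=c))
    return patches


def _fg_fraction(pixels: np.ndarray, threshold: float) -> float:
    return float(np.mean(pixels > threshold))


def threshold_filter(patches: Sequence[Instance], cfg: BagBuildConfig) -> List[Instance]:
    """Drop background patches: keep those with enough above-threshold pixels."""
    if not patches:
        raise ValueError("no patches to filter")
    cfg.validate()
    kept = [
        p
        for p in patches
        if _fg_fraction(p.pixels, cfg.foreground_threshold) >= cfg.min_foreground_fraction
    ]
    if not kept:
        raise EmptyBagError("empty bag after filtering")
    return kept


def balance_bag(
    patches: Sequence[Instance],
    cfg: BagBuildConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Instance]:
    """Bring a bag to exactly ``target_bag_size`` instances.

    Oversized bags keep the patches with the highest foreground fraction
    (ties broken by lower row-major grid index, preserving input order in the
    result).  Undersized bags are topped up with augmented copies: the i-th
    appended copy uses source patch ``i % n`` and the transform
    ``AUGMENTATIONS[(i // n) % 8]``, i.e. the transform list is cycled
    round-robin over the surviving patches.  The procedure is deterministic;
    ``rng`` is accepted for interface stability but unused.
    """
    if not patches:
        raise ValueError("no patches to balance")
    cfg.validate()
    patches = list(patches)
    n, target = len(patches), cfg.target_bag_size
    if n == target:
        return patches
    if n > target:
        grid_index = lambda p: p.grid_row * cfg.grid_cols + p.grid_col
        ranked = sorted(
            range(n),
            key=lambda i: (-_fg_fraction(patches[i].pixels, cfg.foreground_threshold), grid_index(patches[i])),
        )
        keep = sorted(ranked[:target])  # preserve original order
        return [patches[i] for i in keep]
    out = list(patches)
    for i in range(target - n):
        src = patches[i % n]
        tag = AUGMENTATIONS[(i // n) % len(AUGMENTATIONS)]
        out.append(
            replace(
                src,
                pixels=_apply_augmentation(src.pixels, tag),
                augmentation_tag=tag,
            )
        )
    return out


def finalize(patches: Sequence[Instance], patch_side: int = 224) -> List[Instance]:
    """Resize every patch to ``patch_side`` square by bilinear interpolation."""
    if not patches:
        raise ValueError("no patches to finalize")
    out = []
    for p in patches:
        if p.pixels.shape == (patch_side, patch_side):
            pix = p.pixels.astype(np.float32)
        else:
            pix = _sk_resize(
                p.pixels, (patch_side, patch_side), order=1, anti_aliasing=False, preserve_range=True
            )
            pix = np.clip(pix, 0.0, 1.0).astype(np.float32)
        out.append(replace(p, pixels=pix))
    return out


def build_bag(
    image: np.ndarray,
    label: int,
    cfg: Optional[BagBuildConfig] = None,
    ground_truth=None,
    bag_id: str = "bag",
    rng: Optional[np.random.Generator] = None,
) -> Bag:
    """Full pipeline: grid_patch -> threshold_filter -> balance_bag -> finalize.

    If ``ground_truth`` is given, every instance's ``hidden_label`` is set
    from its grid cell; augmented copies inherit their source patch's label.
    Hidden labels are evaluation-only and never visible to training.
    """
    if cfg is None:
        cfg = BagBuildConfig()
    cfg.validate()
    if label not in (0, 1, 2):
        raise ValueError(f"bag label must be in {{0,1,2}}, got {label!r}")
    patches = grid_patch(image, cfg.grid_rows, cfg.grid_cols)
    if ground_truth is not None:
        labels = ground_truth.instance_labels
        for p in patches:
            p.hidden_label = int(labels[p.grid_row * cfg.grid_cols + p.grid_col])
    patches = threshold_filter(patches, cfg)
    patches = balance_bag(patches, cfg, rng)
    patches = finalize(patches, cfg.patch_side)
    return Bag(bag_id=bag_id, instances=patches, label=int(label))


def load_bags(in_dir: str) -> List[Bag]:
    """Read bags written by :func:`save_bags` (patch PNGs + bags.jsonl)."""
    root = Path(in_dir)
    bags = []
    for line in (root / "bags.jsonl").read_text().splitlines():
        rec = json.loads(line)
        hidden = rec.get("hidden_labels")
        instances = []
        for j, rel in enumerate(rec["patch_paths"]):
            pix = iio.imread(root / rel).astype(np.float32) / 255.0
            stem = Path(rel).stem  # r{row}c{col}_{aug}[_{n}]
            rc, rest = stem.split("_", 1)
            row, col = rc[1:].split("c")
            tag = rest.rsplit("_", 1)[0] if rest.rsplit("_", 1)[-1].isdigit() else rest
            instances.append(
                Instance(
                    pixels=pix,
                    grid_row=int(row),
                    grid_col=int(col),
                    augmentation_tag=tag,
                    hidden_label=None if hidden is None else int(hidden[j]),
                )
            )
        bags.append(Bag(bag_id=rec["bag_id"], instances=instances, label=int(rec["label"])))
    return bags


def save_bags(bags: Sequence[Bag], out_dir: str) -> None:
    """Write each bag as patch PNGs plus a JSON-lines bag manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for bag in bags:
        bdir = out / bag.bag_id
        bdir.mkdir(exist_ok=True)
        paths = []
        seen = {}
        for inst in bag.instances:
            stem = f"r{inst.grid_row}c{inst.grid_col}_{inst.augmentation_tag}"
            seen[stem] = seen.get(stem, 0) + 1
            if seen[stem] > 1:
                stem = f"{stem}_{seen[stem]}"
            fname = f"{stem}.png"
            iio.imwrite(bdir / fname, (np.clip(inst.pixels, 0, 1) * 255).round().astype(np.uint8))
            paths.append(f"{bag.bag_id}/{fname}")
        rec = {"bag_id": bag.bag_id, "label": bag.label, "patch_paths": paths}
        if all(inst.hidden_label is not None for inst in bag.instances):
            rec["hidden_labels"] = [int(inst.hidden_label) for inst in bag.instances]
        lines.append(json.dumps(rec, sort_keys=True))
    (out / "bags.jsonl").write_text("\n".join(lines) + "\n")
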