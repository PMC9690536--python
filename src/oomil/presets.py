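"""Canonical study configurations.

Two scales are bundled:

* ``mammogram_scale`` — the full-size conditions: 448x224 images on a
  14-row x 7-column grid (98 patches), dark borders that the threshold
  filter removes, bags balanced to 70 instances of 224x224, and the
  full-size scoring network.  This is the configuration the bag-construction
  and architecture guarantees are stated for.

* ``easy_study`` — a compact, high-contrast regime sized for 1-CPU
  experiments: 192x96 images on a 6x3 grid (18 instances per bag, no dark
  border), 5-7 cell-anchored lesions per positive bag, and the same network
  family at 28px input (a grid patch holds 32x32 pixels of information, so
  nothing is lost at this resolution).  Training-dynamics demonstrations
  (key-instance precision trends, instance-level learning) use this regime.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bag_builder import BagBuildConfig, build_bag
from .network import NetworkSpec
from .synthetic_data import SynthConfig, generate_dataset, make_instance_test_set
from .trainer import TrainConfig

__all__ = ["StudyPreset", "mammogram_scale", "easy_study", "build_study_bags", "study_test_set"]


@dataclass
class StudyPreset:
    synth: SynthConfig
    bags: BagBuildConfig
    network: NetworkSpec
    train: TrainConfig


def mammogram_scale(seed: int = 0, n_bags_per_class: int = 10, epochs: int = 5) -> StudyPreset:
    """Full-size conditions: 98-patch grids, 70-instance bags, 224px net."""
    return StudyPreset(
        synth=SynthConfig(n_bags_per_class=n_bags_per_class, seed=seed),
        bags=BagBuildConfig(),
        network=NetworkSpec(),
        train=TrainConfig(epochs=epochs, seed=seed),
    )


def easy_study(seed: int = 0, n_bags_per_class: int = 30, epochs: int = 12) -> StudyPreset:
    """Compact high-contrast conditions for CPU-scale training runs."""
    return StudyPreset(
        synth=SynthConfig(
            image_height=192,
            image_width=96,
            grid_rows=6,
            grid_cols=3,
            border_margin=0,
            n_lesions_range=(5, 7),
            n_bags_per_class=n_bags_per_class,
            seed=seed,
        ),
        bags=BagBuildConfig(grid_rows=6, grid_cols=3, target_bag_size=18, patch_side=28),
        network=NetworkSpec(input_side=28),
        train=TrainConfig(k=4, epochs=epochs, seed=seed),
    )


def build_study_bags(preset: StudyPreset):
    """Generate the preset's images and build their bags (with hidden labels)."""
    records = generate_dataset(preset.synth)
    return [
        build_bag(img, gt.bag_label, preset.bags, ground_truth=gt, bag_id=bag_id)
        for bag_id, img, gt in records
    ]


def study_test_set(preset: StudyPreset, n_per_class: int = 10):
    """The preset's labeled ROI patch set, at the preset's patch size."""
    return make_instance_test_set(preset.synth, n_per_class, patch_side=preset.bags.patch_side)
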