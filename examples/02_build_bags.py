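"""Turn a whole image into a bag of 70 instances of 224x224.

Pipeline: 14x7 grid (98 patches) -> threshold filter (drops the dark
border patches) -> balancing by flip/rotate augmentation -> bilinear
resize to 224x224.
"""

import numpy as np

from oomil import BagBuildConfig, SynthConfig, build_bag, generate_image, grid_patch, threshold_filter

cfg = SynthConfig(n_bags_per_class=1, seed=4)
img, gt = generate_image(cfg, bag_label=2, rng=np.random.default_rng(4))

patches = grid_patch(img, 14, 7)
survivors = threshold_filter(patches, BagBuildConfig())
bag = build_bag(img, 2, ground_truth=gt, bag_id="demo")
n_aug = sum(i.augmentation_tag != "none" for i in bag.instances)

print(f"grid patches:            {len(patches)}")
print(f"after threshold filter:  {len(survivors)}")
print(f"final bag size:          {len(bag.instances)} (of which {n_aug} augmented copies)")
print(f"instance shape:          {bag.instances[0].pixels.shape}")
print(f"max hidden grade in bag: {max(i.hidden_label for i in bag.instances)} (= bag label {bag.label})")

# 98 -> 60 -> 70: the dark border ring fails the foreground threshold and
# flip/rotate copies of the brightest survivors restore the fixed bag size.
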