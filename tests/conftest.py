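import numpy as np
import pytest

from oomil import SynthConfig, generate_image
from oomil.network import NetworkSpec


@pytest.fixture(scope="session")
def default_synth_cfg():
    return SynthConfig(n_bags_per_class=2, seed=7)


@pytest.fixture(scope="session")
def cancer_image(default_synth_cfg):
    """One full-size synthetic image with bag label 2 plus its ground truth."""
    return generate_image(default_synth_cfg, 2, np.random.default_rng(11))


@pytest.fixture(scope="session")
def tiny_spec():
    """A small network of the same family for gradient-level tests.

    Sides: conv1 16->12, pool 12->6, conv2 6->4, flatten 320.
    """
    return NetworkSpec(input_side=16)
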