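import numpy as np
import pytest

from fallgcn.graph_topology import builtin_layout
from fallgcn.network import ModelConfig, ModelParams
from fallgcn.skeleton_io import SkeletonSequence


@pytest.fixture
def ntu25():
    return builtin_layout("ntu25")


@pytest.fixture
def body25():
    return builtin_layout("body25")


@pytest.fixture
def path5():
    return builtin_layout("toy-path-5")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sequence(layout, T=6, seed=0, coord_channels=3, label=None):
    """Random dense skeleton sequence for a layout."""
    r = np.random.default_rng(seed)
    values = r.normal(0, 1, size=(3, T, layout.V))
    return SkeletonSequence(values, layout, label=label,
                            coord_channels=coord_channels)


@pytest.fixture
def tiny_config():
    """Smallest config that exercises every stage (toy 5-joint path)."""
    return ModelConfig(layout_name="toy-path-6", C1=2,
                       block_channels=(4, 8, 12), Kt=3,
                       mtcn_kernels=(3, 5), mtcn_branch_width=4,
                       num_classes=3)


@pytest.fixture
def tiny_params(tiny_config):
    return ModelParams(tiny_config, seed=3, dtype=np.float64)
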