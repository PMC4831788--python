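import numpy as np
import pytest

from sfconn import (
    RegionAtlas,
    SyntheticConfig,
    build_edge_index,
    default_atlas,
    generate_connectome_stacks,
    generate_coupled_panels,
)


@pytest.fixture
def tiny_atlas():
    """Three regions: two left, one right."""
    return RegionAtlas.from_labels(["lh_A", "lh_B", "rh_A"])


@pytest.fixture
def small_atlas():
    """Six-region bilateral atlas."""
    return default_atlas(6)


@pytest.fixture
def small_index(small_atlas):
    return build_edge_index(small_atlas)


@pytest.fixture
def coupled_stacks():
    """17-subject stacks on a 25-region atlas (300 edges) with strong coupling."""
    cfg = SyntheticConfig(m=17, n=26, coupling=3.0, s_x=8, s_y=8,
                          missing_rate=0.03, seed=11)
    X, Y, truth = generate_coupled_panels(cfg)
    struct, func = generate_connectome_stacks(cfg, X, Y)
    return cfg, struct, func, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
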