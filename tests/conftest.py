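import numpy as np
import pytest

from vrloc import SourcePosition, build_source_array
from vrloc.synth import HeadModelConfig, apply_hmd_model, spherical_head_brir


@pytest.fixture(scope="session")
def array27():
    return build_source_array()


@pytest.fixture(scope="session")
def horizontal_pairs():
    """With/without-HMD BRIR pairs on the horizontal plane (default configs)."""
    pairs = {}
    for az in (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0):
        base = spherical_head_brir(SourcePosition(az, 0.0), HeadModelConfig())
        pairs[az] = (apply_hmd_model(base, seed=int(az)), base)
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
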