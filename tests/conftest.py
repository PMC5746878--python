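import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pulmoquant.phantom import PhantomSpec, generate_vessel_tree, rasterize_phantom


#: Compact phantom used by most unit tests (fast; ~0.5 s to render).
UNIT_SPEC = PhantomSpec(grid_shape=(96, 96, 96), spacing_mm=(1.8, 1.8, 1.8),
                        target_vessel_volume_cm3=40.0, seed=7)


@pytest.fixture(scope="session")
def unit_phantom():
    """One rendered phantom (CT + truth) shared across the session."""
    ct, truth = rasterize_phantom(UNIT_SPEC)
    return UNIT_SPEC, ct, truth


@pytest.fixture(scope="session")
def unit_tree():
    return generate_vessel_tree(UNIT_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
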