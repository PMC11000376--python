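import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_roi(rng):
    """Random 4x4x2 quantised label ROI (levels 1..4, no outside voxels)."""
    return rng.integers(1, 5, size=(4, 4, 2)).astype(np.int32)


@pytest.fixture
def masked_roi(rng):
    """Random 5x4x3 label volume with ~30% of voxels outside the ROI (0)."""
    lab = rng.integers(1, 5, size=(5, 4, 3)).astype(np.int32)
    lab[rng.random(lab.shape) < 0.3] = 0
    if (lab > 0).sum() < 2:
        lab[0, 0, 0] = lab[0, 0, 1] = 1
    return lab


@pytest.fixture
def phantom_volume(rng):
    vol = rng.normal(0.0, 1.0, size=(24, 24, 24))
    mask = np.zeros(vol.shape, dtype=np.uint8)
    mask[8:17, 7:18, 9:16] = 1
    return vol, mask
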