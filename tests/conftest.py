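import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from wsqeeg import Recording  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240605)


@pytest.fixture
def white_recording(rng):
    """Two-channel white-noise recording, 60 s at 250 Hz."""
    return Recording(rng.standard_normal((2, 15000)), 250.0, ["Fp1", "Fp2"])


@pytest.fixture
def montage_recording(rng):
    """Full 19-channel white-noise recording, 30 s at 250 Hz."""
    from wsqeeg import MONTAGE_1020
    data = rng.standard_normal((19, 7500))
    return Recording(data, 250.0, list(MONTAGE_1020), subject_id="fix")
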