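from __future__ import annotations

import numpy as np
import pytest

from telotype.alignment import ScoringParams
from telotype.repeat_model import load_repeat_set


@pytest.fixture(scope="session")
def rs():
    return load_repeat_set()


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
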