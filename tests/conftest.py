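import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from saccatk import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_step_plan():
    """Twenty noiseless step-task trials, one per 45-deg direction at 10 deg."""
    dirs = [0.0, 45.0, 90.0, 135.0, 180.0, -135.0, -90.0, -45.0]
    trials = [
        synthgen.PlannedTrial(fixation_ms=800.0 + 37.0 * i, target_direction_deg=dirs[i % 8],
                              target_eccentricity_deg=10.0)
        for i in range(20)
    ]
    return synthgen.TracePlan(sampling_rate=1000.0, trials=trials, seed=7)
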