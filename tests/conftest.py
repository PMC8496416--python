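import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from oknlab import DetectorConfig, OKNGenParams, StimulusSpec
from oknlab.simulator import synth_fixation_trace, synth_okn_trace


@pytest.fixture
def config():
    return DetectorConfig()

@pytest.fixture
def stimulus():
    return StimulusSpec(sf_cpd=1.5, contrast=0.33, direction=1)


@pytest.fixture
def okn_trace(stimulus):
    """A default saw-tooth OKN trial (seeded)."""
    return synth_okn_trace(stimulus, OKNGenParams(), seed=1234)


@pytest.fixture
def fixation_trace():
    return synth_fixation_trace(OKNGenParams(), seed=99)


@pytest.fixture
def clean_gen():
    """Near-noiseless, blink-free generator parameters.

    Strictly zero noise makes the median-based threshold degenerate
    (eta = 0, every moving sample supra-threshold), so 'clean' traces carry
    a tiny sensor noise that keeps the detector well-defined while making
    detection essentially deterministic.
    """
    return OKNGenParams(
        position_noise_sd_deg=0.005,
        binocular_disparity_noise_deg=0.002,
        blink_rate_hz=0.0,
    )


@pytest.fixture
def zero_noise_gen():
    """Exactly deterministic generator (for ground-truth bookkeeping tests)."""
    return OKNGenParams(
        position_noise_sd_deg=0.0,
        binocular_disparity_noise_deg=0.0,
        blink_rate_hz=0.0,
    )
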