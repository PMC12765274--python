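import numpy as np
import pytest

from chirpsifter.pulse_shapes import (
    ChirpPulse,
    PI_HALF_QCRIT,
    amplitude_for_qcrit,
)


@pytest.fixture
def pi2_pulse():
    """100 ns / 500 MHz WURST pi/2 pulse (Q = 2 ln2 / pi)."""
    return ChirpPulse(
        tp=100.0, sweep=500.0,
        nu1=amplitude_for_qcrit(PI_HALF_QCRIT, 100.0, 500.0),
        n=16.0, role="pi/2",
    )


@pytest.fixture
def pi_pulse():
    """100 ns / 500 MHz WURST pi pulse at Q = 5."""
    return ChirpPulse(
        tp=100.0, sweep=500.0,
        nu1=amplitude_for_qcrit(5.0, 100.0, 500.0),
        n=16.0, role="pi",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
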