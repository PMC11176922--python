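import logging

import numpy as np
import pytest

from cyclopred import BreathingSignal, SyntheticConfig, generate_trace

logging.getLogger("cyclopred").setLevel(logging.ERROR)

RATE = 20.0


@pytest.fixture
def cosine_signal():
    """y(t) = 5 + 5 cos(2 pi t / 4), 60 s at 20 Hz: the exact model form."""
    t = np.arange(int(60 * RATE) + 1) / RATE
    y = 5.0 + 5.0 * np.cos(2 * np.pi * t / 4.0)
    return BreathingSignal(t=t, y=y, rate_hz=RATE)


@pytest.fixture
def clean_constant_trace():
    """Noise-free constant-parameter synthetic trace (exact raised cosine)."""
    cfg = SyntheticConfig(duration_s=60, noise_sd_mm=0.0,
                          amplitude_drift=(0.0, 60.0),
                          baseline_drift_mm=(0.0, 90.0),
                          period_s=(4.0, 0.0), amplitude_mm=(10.0, 0.0),
                          seed=0)
    return generate_trace(cfg)


@pytest.fixture
def modulated_trace():
    """Drifting, shaped, noise-free trace exercising the full decomposition."""
    cfg = SyntheticConfig(duration_s=120, noise_sd_mm=0.0,
                          exhale_rest_exponent=2.0, seed=7)
    return generate_trace(cfg)
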