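import numpy as np
import pytest

from phytoephys import (
    APShapeParams,
    NoiseModel,
    SessionProtocol,
    WASPShapeParams,
    generate_vft_ap,
    generate_wasp,
)


@pytest.fixture
def quiet_noise():
    """Noise model with every disturbance switched off."""
    return NoiseModel(baseline_sd=0, drift_amp=0, mains_amp_50hz=0, laser_amp_40hz=0)


@pytest.fixture
def ap_clean():
    """Deterministic noise-free AP template: 40 mV, 1 kHz, onset 20 s."""
    return generate_vft_ap(
        APShapeParams(jitter=0.0), fs=1000, duration_s=30, seed=0, onset_s=20.0
    )


@pytest.fixture
def wasp_clean():
    """Deterministic noise-free WASP template: 30 mV, laser at 20 s."""
    tr = generate_wasp(
        WASPShapeParams(tail_variability=0.0), fs=1000, duration_s=120, seed=0, onset_s=20.0
    )
    tr.events = [("laser_on", 20.0), ("laser_off", 21.0)]
    return tr


@pytest.fixture
def short_protocol():
    return SessionProtocol(baseline_s=20.0, post_s=10.0, fs_acquire=100.0, n_trials=3, seed=7)


def sine(f, fs, duration, amp=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * f * t + phase), t
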