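"""Shared fixtures: small, fast synthetic recordings."""

import numpy as np
import pytest

from chemoreflex import SignalRecording, SynthConfig, simulate_subject


@pytest.fixture(scope="session")
def fast_config() -> SynthConfig:
    """Reduced-rate, 4-administration configuration for quick unit tests."""
    return SynthConfig(seed=11, sample_rate=125.0, n_admins=4)


@pytest.fixture(scope="session")
def fast_recording(fast_config):
    return simulate_subject(fast_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SynthConfig:
    return SynthConfig(
        seed=5,
        sample_rate=125.0,
        n_admins=4,
        noise_sd_ventilation=0.0,
        noise_sd_hr=0.0,
        noise_sd_etco2=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_config):
    return simulate_subject(noiseless_config)


def make_flat_recording(
    duration=400.0,
    fs=50.0,
    spo2_value=96.0,
    n2_intervals=((260.0, 280.0),),
    rr=1.0,
):
    """Minimal hand-built recording: flat SpO2, no flow, regular beats."""
    n = int(duration * fs)
    beat_times = np.arange(0.5, duration - 0.5, rr)
    return SignalRecording(
        sample_rate=fs,
        flow=np.zeros(n),
        spo2=np.full(n, float(spo2_value)),
        beat_times=beat_times,
        n2_intervals=np.asarray(n2_intervals, dtype=float),
    )
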