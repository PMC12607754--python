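import numpy as np
import pytest

from oscsync import (
    ProtocolEvents,
    SimulationConfig,
    Trace,
    TraceKind,
    TraceSet,
)


def sinusoid_trace(freq_hz=0.2, duration_s=600.0, fs_hz=5.0, amp=1.0,
                   phase=0.0, label="sin", offset=0.0):
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    return Trace(t, offset + amp * np.sin(2 * np.pi * freq_hz * t + phase), label)


def white_noise_set(seed, m=10, n=3000, fs_hz=5.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs_hz
    return TraceSet(tuple(
        Trace(t, rng.standard_normal(n), f"w{i}") for i in range(m)
    ))


@pytest.fixture
def identical_sinusoids():
    tr = sinusoid_trace()
    return TraceSet(tuple(
        Trace(tr.time_s, tr.values, f"ROI{i}") for i in range(10)
    ))


@pytest.fixture
def noise_set():
    return white_noise_set(7)


@pytest.fixture
def blocker_events():
    return ProtocolEvents(applications=((150.0, "trigger"), (450.0, "blocker")))


@pytest.fixture
def short_sim_config():
    """Reduced-duration simulation for fast unit tests."""
    return SimulationConfig(duration_s=450.0, seed=11)
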