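import numpy as np
import pytest

from sensorqc import FeatureSeries, SensorRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_accel():
    """A 10-s, 120 Hz accel recording: gravity + 2 Hz gait-like sine."""
    t = np.arange(1200) / 120.0
    sine = 1.5 * np.sin(2 * np.pi * 2.0 * t)
    samples = np.column_stack([0.2 * sine, sine, 9.81 + 0.5 * sine])
    return SensorRecording(t, samples, nominal_rate=120.0, modality="accel")


@pytest.fixture
def bimodal_energy(rng):
    """A voice-like frame-energy series: loud phonation vs near-silence."""
    truth = np.where((np.arange(2000) // 400) % 2 == 0, 2, 1)
    vals = np.where(truth == 1, rng.normal(50.0, 5.0, 2000),
                    rng.normal(0.5, 0.2, 2000))
    fs = FeatureSeries(np.abs(vals), rate=100.0, feature_kind="frame_energy")
    return fs, truth
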