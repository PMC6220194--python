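import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from padflux.synthetic import EventStream, NoiseModel

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def clean_noise():
    """Noise-free, jitter-free signal model: exact 4e-3 deg peaks, 20 ms FWHM."""
    return NoiseModel(
        gaussian_sd=0.0,
        drift_amplitude=0.0,
        peak_amplitude_log_sd=0.0,
        peak_width_sd=0.0,
    )


@pytest.fixture
def default_noise():
    return NoiseModel()


def make_events(times, unit_id="u", budded=None):
    times = np.asarray(times, dtype=float)
    if budded is None:
        budded = np.zeros(times.size, dtype=bool)
    return EventStream(unit_id, times, budded)
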