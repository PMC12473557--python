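import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neowear.io_recordings import ChannelRole, TimeSeriesChannel
from neowear.synthetic import SimulationSpec

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def short_spec() -> SimulationSpec:
    """A 30 min simulated day with one sensor adjustment and one low-SNR
    episode, sized for fast unit tests."""
    return SimulationSpec(
        duration_s=1800.0,
        wireless_snr_db=((0.0, 5.0), (900.0, -5.0), (1500.0, 5.0)),
        sensor_removal_events=(("SA", 300.0, 360.0),),
        care_annotations=(("RC", 200.0, 500.0),),
        seed=42,
    )


@pytest.fixture
def spo2_channel() -> TimeSeriesChannel:
    rng = np.random.default_rng(0)
    values = 95.0 + np.cumsum(rng.normal(0, 0.2, 600)).clip(-5, 4)
    return TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0, values)


def make_channel(role, values, rate=None, start=0.0):
    from neowear.io_recordings import NOMINAL_RATE_HZ

    return TimeSeriesChannel(
        role, start, rate if rate is not None else NOMINAL_RATE_HZ[role],
        np.asarray(values, dtype=float),
    )
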