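import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mobisense import LocationTrace, PreprocessConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def cfg() -> PreprocessConfig:
    return PreprocessConfig()


def make_trace(t, lat, lon, tz_offset=0.0, pid="t") -> LocationTrace:
    return LocationTrace(pid, np.asarray(t, float), np.asarray(lat, float),
                         np.asarray(lon, float), tz_offset=tz_offset)


@pytest.fixture
def trace_factory():
    return make_trace
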