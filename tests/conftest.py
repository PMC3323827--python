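import numpy as np
import pytest
from hypothesis import settings

from gcalign.peaks import Peak, PeakTable, Spectrum

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_peak(pid, rid="run0", rt1=10.0, rt2=2.0, area=100.0, spec=None,
              name=None, cas=None):
    spec = spec if spec is not None else Spectrum(
        np.array([50.0, 60.0, 70.0]), np.array([10.0, 5.0, 1.0])
    )
    return Peak(peak_id=pid, run_id=rid, rt1=rt1, rt2=rt2, area=area,
                spectrum=spec, name=name, cas=cas)


@pytest.fixture
def simple_spectrum():
    return Spectrum(np.array([50.0, 60.0, 70.0]), np.array([10.0, 5.0, 1.0]))


@pytest.fixture
def three_peak_table():
    return PeakTable("run0", [
        make_peak("p1", rt1=10.0, rt2=2.0),
        make_peak("p2", rt1=20.0, rt2=3.0),
        make_peak("p3", rt1=30.0, rt2=4.0),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
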