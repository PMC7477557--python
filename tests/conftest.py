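import numpy as np
import pytest
from hypothesis import settings

from gravseq.simulate import FlightPlan, VibrationModel, make_flight

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: vibration model with peaks below the 250 Hz Nyquist of the cheap traces
LOWFREQ_VIB = VibrationModel(
    peak_freqs=(60.0, 120.0, 200.0), peak_rms=(0.015, 0.010, 0.008)
)

ONE_SET_PLAN = FlightPlan(sets=(5,), lead_in_s=60.0, lead_out_s=60.0)


@pytest.fixture(scope="session")
def small_flight():
    """One-set flight at 500 Hz: (trace, truth periods). ~420 s."""
    return make_flight(plan=ONE_SET_PLAN, vib=LOWFREQ_VIB, seed=0,
                       sample_rate=500.0)


@pytest.fixture(scope="session")
def full_flight_2k():
    """Full 5+6+4+5 plan at 2 kHz with the default vibration model."""
    return make_flight(seed=1, sample_rate=2000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
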