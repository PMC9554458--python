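import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")

from gentapbpk import (  # noqa: E402
    ConcentrationProfile,
    DosingRegimen,
    PBPKParameters,
    simulate_profile,
)


@pytest.fixture(scope="session")
def preterm():
    return PBPKParameters.preterm()


@pytest.fixture(scope="session")
def term():
    return PBPKParameters.term()


@pytest.fixture(scope="session")
def extended_q48():
    return DosingRegimen(dose_per_kg=6.0, interval=48.0)


@pytest.fixture(scope="session")
def conventional_q24():
    return DosingRegimen(dose_per_kg=4.0, interval=24.0)


@pytest.fixture(scope="session")
def preterm_extended_profile(preterm, extended_q48):
    return simulate_profile(preterm, extended_q48, dt=0.05)


@pytest.fixture
def make_profile(preterm):
    """Factory for hand-built blood curves (tissue curves zeroed)."""

    def _make(times, cb, interval=24.0, dose_per_kg=6.0):
        times = np.asarray(times, dtype=float)
        cb = np.asarray(cb, dtype=float)
        zeros = np.zeros_like(cb)
        regimen = DosingRegimen(dose_per_kg=dose_per_kg, interval=interval)
        return ConcentrationProfile(
            times=times, Cb=cb, Ch=zeros, Ck=zeros, Cr=zeros, A_elim=zeros,
            params=preterm, regimen=regimen,
        )

    return _make
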