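import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from camfret.protocol import SOMA_50_AT_20HZ, StimulusProtocol
from camfret.records import TraceRecord
from camfret.simulate import (
    SOMA_ACQUISITION,
    CalciumParams,
    get_preset,
    simulate_ca_transient,
    simulate_kinase,
    simulate_recording,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

NOISE_FREE = SOMA_ACQUISITION.replace(
    noise_sd_per_channel=0.0, artifact_magnitude=0.0, duration=45.0
)


@pytest.fixture(scope="session")
def wt_params():
    return get_preset("WT")


@pytest.fixture(scope="session")
def p212l_params():
    return get_preset("P212L")


@pytest.fixture(scope="session")
def soma_protocol():
    return SOMA_50_AT_20HZ


@pytest.fixture(scope="session")
def noise_free_acq():
    return NOISE_FREE


@pytest.fixture(scope="session")
def wt_noise_free_record(wt_params, soma_protocol):
    return simulate_recording(wt_params, soma_protocol, acq=NOISE_FREE)


@pytest.fixture(scope="session")
def wt_activation(wt_params, soma_protocol):
    t, ca = simulate_ca_transient(soma_protocol, CalciumParams(), 45.0, dt=0.002)
    return simulate_kinase(ca, t, 1.0, wt_params)


def make_record(cfp, yfp=None, rfp=None, times=None, protocol=None, **kw):
    """Small hand-built TraceRecord for unit tests."""
    cfp = np.asarray(cfp, dtype=float)
    n = len(cfp)
    if times is None:
        times = np.arange(n, dtype=float)
    return TraceRecord(
        roi_id=kw.pop("roi_id", "test"),
        genotype=kw.pop("genotype", "WT"),
        protocol=protocol,
        frame_times=np.asarray(times, dtype=float),
        cfp=cfp,
        yfp=np.full(n, 100.0) if yfp is None else np.asarray(yfp, dtype=float),
        rfp=np.full(n, 100.0) if rfp is None else np.asarray(rfp, dtype=float),
        **kw,
    )
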