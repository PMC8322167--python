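import logging

import numpy as np
import pytest

from bim import InjuryScenario, default_protocol, synthesize_recording
from bim.simulate import ArtifactSpec

logging.getLogger("bim").setLevel(logging.ERROR)

#: Envelope sample rate used throughout the tests. All event metrics act on
#: 10 s slot means, whose statistics are essentially rate-independent, so a
#: reduced rate keeps full-protocol simulations cheap.
FAST_RATE_HZ = 5.0


def clean_scenario(**overrides) -> InjuryScenario:
    """Noise-free, drift-free, artifact-free scenario for exact oracles."""
    base = dict(
        noise_sd_ohm=0.0, icp_noise_sd_mmhg=0.0,
        drift_linear_ohm_per_h=0.0, settle_amplitude_ohm=0.0,
        artifacts=ArtifactSpec(), sample_rate_hz=FAST_RATE_HZ, seed=0)
    base.update(overrides)
    return InjuryScenario(**base)


@pytest.fixture(scope="session")
def default_scenario() -> InjuryScenario:
    return InjuryScenario(sample_rate_hz=FAST_RATE_HZ, seed=42)


@pytest.fixture(scope="session")
def default_recording(default_scenario):
    """One full-protocol recording at the default study conditions."""
    return synthesize_recording(default_scenario)


@pytest.fixture(scope="session")
def clean_recording():
    """Deterministic noise-free recording for exact value checks."""
    return synthesize_recording(clean_scenario())


@pytest.fixture()
def protocol():
    return default_protocol()


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: draws are order-independent."""
    return np.random.default_rng(20260922)
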