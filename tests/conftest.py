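import numpy as np
import pytest
from hypothesis import settings

import mbcea

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """The bundled base-case parameter set."""
    return mbcea.load_default_config()


@pytest.fixture(scope="session")
def psa_default(config):
    """One full 1,000-iteration PSA run at a fixed seed, shared read-only."""
    return mbcea.run_psa(config, seed=20220602)


@pytest.fixture(scope="session")
def reconstruction_roundtrip():
    """simulate -> digitize -> reconstruct -> fit, one arm at n = 2000.

    Emulates reading event times off a published survival figure: a
    median-9-month exponential arm with 24-month administrative follow-up,
    curve sampled on a half-month grid with numbers at risk.
    """
    spec = mbcea.TrialSpec(n_per_arm=2000, efs_median=9.0, os_median=19.0,
                           shape=1.0, admin_censor_time=24.0, seed=42)
    records = mbcea.simulate_trial(spec)
    km = mbcea.km_inputs_from_trial(records, grid_step=0.5)
    ipd = mbcea.reconstruct_ipd(km["efs"])
    fitted = mbcea.fit_parametric(ipd, "exponential")
    return spec, records, km, ipd, fitted


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
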