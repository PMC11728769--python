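import numpy as np
import pytest

import oncopop as op


@pytest.fixture(scope="session")
def coefs():
    return op.default_coefficient_set()


@pytest.fixture(scope="session")
def residuals():
    return op.default_residual_spec()


@pytest.fixture(scope="session")
def zero_residuals():
    return op.ResidualSpec(stages={})


@pytest.fixture(scope="session")
def reference_spec():
    return op.reference_population(n=3000, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(reference_spec, coefs, zero_residuals):
    """Reference cohort simulated with all residual sds at zero."""
    profiles = op.sample_primaries(reference_spec, np.random.default_rng(11))
    return op.simulate_cohort(profiles, coefs, zero_residuals, None)


@pytest.fixture(scope="session")
def noisy_cohort(coefs, residuals):
    """A 20000-patient reference cohort with the shipped residual models."""
    spec = op.reference_population(n=20000, seed=5)
    rng = np.random.default_rng(5)
    profiles = op.sample_primaries(spec, rng)
    return op.simulate_cohort(profiles, coefs, residuals, rng)
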