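"""Shared fixtures: mode coefficients and a couple of cached short runs."""

import numpy as np
import pytest

from tcalpha.integrator import IntegrationConfig, simulate
from tcalpha.model import ExcitabilityDistribution, derive_mode_coefficients
from tcalpha.network import build_default_network


@pytest.fixture(scope="session")
def coeffs():
    return derive_mode_coefficients(ExcitabilityDistribution())


# session-scoped alias usable inside hypothesis-driven tests (hypothesis
# disallows function-scoped fixtures but session scope is safe)
@pytest.fixture(scope="session")
def coeffs_session(coeffs):
    return coeffs


@pytest.fixture(scope="session")
def short_sim(coeffs):
    """22-s reference-condition run (CSF 0.6), shared across tests."""
    spec = build_default_network(csf=0.6)
    cfg = IntegrationConfig(duration=22.0, burn_in=2.0, seed=11)
    return simulate(spec, coeffs, cfg)


@pytest.fixture(scope="session")
def disconnected_sim(coeffs):
    """22-s disconnected run (CSF 0.0), shared across tests."""
    spec = build_default_network(csf=0.0)
    cfg = IntegrationConfig(duration=22.0, burn_in=2.0, seed=11)
    return simulate(spec, coeffs, cfg)
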