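"""Shared fixtures: published parameter sets and pre-simulated samples.

Expensive Monte-Carlo samples are session-scoped so several tests can
share one simulation run.
"""

import numpy as np
import pytest

from ringrupture import (
    BondModel,
    PullingProtocol,
    simulate_rupture_distribution,
)

HEAD = BondModel(k0_per_s=0.0027, delta_nm=1.23)
HINGE = BondModel(k0_per_s=0.0025, delta_nm=1.61)
STRONG = BondModel(k0_per_s=2.7e-5, delta_nm=0.8)  # high-force (70 pN) interface
PEAK20 = BondModel(k0_per_s=0.0021, delta_nm=1.23)  # low-force crosslinked subpopulation


@pytest.fixture(scope="session")
def protocol():
    return PullingProtocol()


@pytest.fixture(scope="session")
def head_bond():
    return HEAD


@pytest.fixture(scope="session")
def hinge_bond():
    return HINGE


@pytest.fixture(scope="session")
def strong_bond():
    return STRONG


@pytest.fixture(scope="session")
def head_sample_4k():
    """4000 rupture events at the head-geometry parameters."""
    return simulate_rupture_distribution(
        PullingProtocol(seed=42), HEAD, n=4000
    )


@pytest.fixture(scope="session")
def head_sample_89():
    """Head-geometry sample at the experimental size (n = 89)."""
    return simulate_rupture_distribution(PullingProtocol(seed=4242), HEAD, n=89)
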