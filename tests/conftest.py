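import warnings

import numpy as np
import pytest

from esfm import (
    BiasSpec,
    CGMapping,
    LinearCV,
    compute_oracle,
    make_builtin_system,
    simulate,
)


@pytest.fixture(scope="session")
def harmonic_1d():
    return make_builtin_system("harmonic_1d")


@pytest.fixture(scope="session")
def mb_system():
    return make_builtin_system("muller_brown")


@pytest.fixture(scope="session")
def x_mapping():
    return CGMapping.axis(2, 0, "x")


@pytest.fixture(scope="session")
def mb_oracle(mb_system, x_mapping):
    return compute_oracle(mb_system, x_mapping, (-3.1, 1.4, 2001))


@pytest.fixture(scope="session")
def harmonic_dataset(harmonic_1d):
    """Unbiased 1D harmonic frames, decorrelated, many chains."""
    return simulate(
        harmonic_1d, BiasSpec(), n_steps=42000, dt=0.05, seed=11,
        stride=40, n_chains=200, burn_in=2000,
    )


@pytest.fixture(scope="session")
def umbrella_harmonic_dataset(harmonic_1d):
    """Harmonic well with a harmonic umbrella (kappa=3) at the origin."""
    bias = BiasSpec(
        kind="harmonic_umbrella", cv=LinearCV([[1.0]]), kappa=3.0, center=[0.0]
    )
    return simulate(
        harmonic_1d, bias, n_steps=42000, dt=0.02, seed=12,
        stride=60, n_chains=200, burn_in=2000,
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="grid extends outside the RBF-center span"
        )
        yield
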