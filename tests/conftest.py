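import numpy as np
import pytest

from dnatwist import REFERENCE_CONSTANTS
from dnatwist.synthetic import (GeneratorSpec, sample_ensemble,
                                DEFAULT_ALPHA_D)


@pytest.fixture(scope="session")
def constants():
    """Reference per-bp elastic constants (1 M NaCl, B-DNA)."""
    return REFERENCE_CONSTANTS


@pytest.fixture(scope="session")
def spec(constants):
    """Default generator: 5×10⁴ frames averaged over 19 bp steps."""
    return GeneratorSpec(constants=constants)


@pytest.fixture(scope="session")
def thermal_spec(constants):
    return GeneratorSpec(constants=constants, alpha_d=DEFAULT_ALPHA_D)


@pytest.fixture(scope="session")
def reference_ensemble(spec):
    """One untilted 5×10⁴-frame ensemble, reused across read-only tests."""
    return sample_ensemble(spec, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
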