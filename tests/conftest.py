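import numpy as np
import pytest

from crypticfold import KineticParams


@pytest.fixture(scope="session")
def truth_params() -> KineticParams:
    """Default kinetic truth used by the synthetic generators."""
    from crypticfold.synthetic import DEFAULT_TRUTH

    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def sharp_params() -> KineticParams:
    """A second parameter set with both enthalpies nonzero."""
    return KineticParams(Ea1=350.0, Tstar1=330.0, Ea2=280.0, Tstar2=338.0,
                         dHcal1=300.0, dHcal2=200.0)


@pytest.fixture(scope="session")
def toy_bundle():
    """Small toy two-state ensemble with a planted exposure patch."""
    from crypticfold.synthetic import gen_toy_ensemble

    return gen_toy_ensemble(seed=11, n_frames=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
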