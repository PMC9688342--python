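import numpy as np
import pytest

from lnlevelseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tiny_phantom():
    """One deterministic half-scale phantom shared across tests."""
    return generate_phantom(PhantomSpec.tiny(seed=3))


@pytest.fixture(scope="session")
def tiny_cases():
    """A small cohort of phantoms for sampler/training tests."""
    return [generate_phantom(PhantomSpec.tiny(seed=s)) for s in (3, 7, 11)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
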