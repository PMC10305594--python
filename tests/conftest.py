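import numpy as np
import pytest

from druseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64x64x32 phantom scan/mask pair."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def tiny_phantom():
    """A 32x32x16 phantom for fast model-in-the-loop tests."""
    spec = PhantomSpec(shape=(32, 32, 16), root_radius=2.0,
                       branching_depth=2, seed=7)
    return generate_phantom(spec)


def random_mask(rng, shape, p=0.2, ensure_nonempty=True):
    m = (rng.random(shape) < p).astype(np.uint8)
    if ensure_nonempty and not m.any():
        m[tuple(s // 2 for s in shape)] = 1
    return m
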