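import numpy as np
import pytest

from rosella.synthetic import NO_NOISE, FieldSpec, generate_rosella_field


@pytest.fixture(scope="session")
def noiseless_field():
    """One noiseless reporter field with its ground truth (shared, read-only)."""
    spec = FieldSpec(noise=NO_NOISE, seed=11)
    return generate_rosella_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
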