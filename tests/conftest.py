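import numpy as np
import pytest

from rnarefold.synthetic import GeneratorConfig


@pytest.fixture
def make_config():
    """Factory for generator configs with a fixed default seed."""

    def _make(**overrides):
        overrides.setdefault("seed", 1234)
        return GeneratorConfig(**overrides)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(99)
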