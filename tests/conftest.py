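import numpy as np
import pytest

from tauread.synthetic import PhantomSpec, generate_pet, generate_segmentation


@pytest.fixture(scope="session")
def seg64():
    """Default 64-cubed schematic parcellation (seed-independent)."""
    return generate_segmentation(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_factory(seg64):
    """Noise-free PET volumes per scenario, cached for the whole session."""
    cache = {}

    def make(scenario, **kwargs):
        key = (scenario, tuple(sorted(kwargs.items())))
        if key not in cache:
            spec = PhantomSpec(scenario=scenario, **kwargs)
            cache[key] = generate_pet(spec, seg64)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230516)
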