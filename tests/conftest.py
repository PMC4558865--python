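import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_population():
    """Three cells with known genes and resources; R_env leaves a free pool."""
    from gsevol.fixtures import ToySpec, make_toy_population

    spec = ToySpec(
        genes=(
            ((0.0, 0.8),),
            ((0.5, 0.6), (-0.5, 0.4)),
            (),
        ),
        resources=(1.0, 2.0, 0.5),
        R_env=10.0,
        alpha=0.2,
    )
    return make_toy_population(spec)
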