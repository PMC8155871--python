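import numpy as np
import pytest

from seedstage.synth import CohortSpec, generate_seed_image


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(rng_seed=7)


@pytest.fixture(scope="session")
def cabinet_image(default_spec):
    """One default synthetic cabinet image with its ground truth."""
    return generate_seed_image(default_spec, rows=8, cols=12,
                               rng=np.random.default_rng(3))
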