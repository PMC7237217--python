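import numpy as np
import pytest

import centrofind as cf


@pytest.fixture(scope="session")
def small_phantom():
    """A modest clustered phantom shared across tests (seed-fixed)."""
    spec = cf.PhantomSpec(shape=(24, 96, 96), n_cells=10, radius=7.0, seed=42)
    vol, truth = cf.generate(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def trained_model(small_phantom):
    """A forest trained on the shared phantom's annotations."""
    spec, vol, truth = small_phantom
    anns = cf.annotations_from_truth(truth[0], spec.shape)
    return cf.train([vol], anns, sigma=spec.radius / 2.0, seed=0)
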