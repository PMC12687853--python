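import numpy as np
import pytest

import thalseg as ts


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic default phantom shared across tests."""
    spec = ts.PhantomSpec()
    t1, pd, labels = ts.make_phantom(spec)
    return spec, t1, pd, labels


@pytest.fixture(scope="session")
def sparse_phantom(default_phantom):
    spec, t1, pd, labels = default_phantom
    return spec, t1, pd, labels, ts.sparsify_labels(labels, spec.erosion_radius)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
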