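import numpy as np
import pytest

from ensemblekit import validate_cube


def random_simplex_cube(rng, n, n_samples, k, strictly_positive=False):
    """Random confidence cube with Dirichlet(1,...,1) rows."""
    values = rng.dirichlet(np.ones(k), size=(n, n_samples))
    if strictly_positive:
        values = (values + 1e-6) / (1.0 + k * 1e-6)
    return validate_cube(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
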