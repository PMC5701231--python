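import numpy as np
import pytest

from lrprop import CountMatrix, clr, replace_zeros
from lrprop.simulate import simulate_modules


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def toy_counts():
    """A small hand-sized matrix: 4 samples x 3 features, no zeros."""
    return CountMatrix(
        np.array(
            [
                [10.0, 20.0, 5.0],
                [12.0, 18.0, 7.0],
                [8.0, 25.0, 4.0],
                [15.0, 30.0, 9.0],
            ]
        ),
        ("s1", "s2", "s3", "s4"),
        ("f1", "f2", "f3"),
    )


@pytest.fixture
def random_counts(rng):
    """20 samples x 30 features of moderately overdispersed counts."""
    return CountMatrix(rng.negative_binomial(5, 0.05, size=(20, 30)).astype(float) + 1.0)


@pytest.fixture
def random_logratios(random_counts):
    return clr(replace_zeros(random_counts))


@pytest.fixture
def proportional_counts(rng):
    """10 x 6 counts where column 'F4' is exactly 3 x column 'F2'."""
    values = rng.integers(1, 500, size=(10, 6)).astype(float)
    values[:, 3] = 3.0 * values[:, 1]
    return CountMatrix(values)


@pytest.fixture
def module_fixture():
    """Two planted proportional modules (loud, quiet) on a 40-feature background."""
    counts, membership = simulate_modules(
        module_sizes=(5, 5), module_log_sd=(1.0, 0.5), n_noise=40, n_samples=20, seed=3
    )
    return counts, membership
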