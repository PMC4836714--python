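import numpy as np
import pytest

from fluxcast.encoding import encode_table, fit_scalers
from fluxcast.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Shared small synthetic dataset (80 samples, noise sd 2)."""
    return generate_dataset(80, seed=11)


@pytest.fixture(scope="session")
def table(dataset):
    return dataset.observed_table()


@pytest.fixture(scope="session")
def scalers(table):
    return fit_scalers(table)


@pytest.fixture(scope="session")
def encoded(table, scalers):
    return encode_table(table, scalers)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mix(rng, substrates=None, n_max=3):
    """A random substrate mix over 1..n_max substrates (helper, not a fixture)."""
    from fluxcast.stoichiometry import SUBSTRATES, SubstrateMix

    pool = list(substrates or SUBSTRATES)
    n = int(rng.integers(1, n_max + 1))
    chosen = rng.choice(len(pool), size=n, replace=False)
    w = rng.dirichlet(np.ones(n))
    return SubstrateMix({pool[i]: float(x) for i, x in zip(chosen, w / w.sum())})
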