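import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from acetdiff.genome_io import GenomeSpec, make_bin_grid

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def small_genome():
    return GenomeSpec((("chr1", 10_000), ("chr2", 6_000)))


@pytest.fixture
def grid(small_genome):
    return make_bin_grid(small_genome, 500)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def nb_counts(rng, mu, alpha, n_samples):
    """NB(mean mu, variance mu + alpha mu^2) matrix, one column per sample."""
    mu = np.asarray(mu, float)
    cols = []
    for _ in range(n_samples):
        if alpha <= 0:
            cols.append(rng.poisson(mu))
        else:
            cols.append(rng.poisson(rng.gamma(1.0 / alpha, mu * alpha)))
    return np.stack(cols, axis=1)


@pytest.fixture
def two_group_counts(rng):
    """10 features x (3 control + 3 case) with no true differences."""
    X = nb_counts(rng, np.full(10, 50.0), 0.05, 6)
    cols = [f"control_{i}" for i in range(3)] + [f"case_{i}" for i in range(3)]
    counts = pd.DataFrame(X, columns=cols)
    conditions = {c: ("control" if "control" in c else "case") for c in cols}
    return counts, conditions
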