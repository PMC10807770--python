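import numpy as np
import pytest

from tpac.gene_sets import GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_collection(rng, n_sets=20, universe_size=100, min_size=3, max_size=15, prefix="G"):
    """Random gene set collection over a synthetic gene universe."""
    universe = [f"{prefix}{j:04d}" for j in range(universe_size)]
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"SET{k:03d}"] = members
    return GeneSetCollection(sets=sets, descriptions={name: f"desc {name}" for name in sets})


@pytest.fixture
def small_expression(rng):
    """20 samples x 30 genes of strictly varying nonnegative expression."""
    n, p = 20, 30
    values = rng.gamma(shape=2.0, scale=3.0, size=(n, p))
    sample_ids = [f"S{i}" for i in range(n)]
    gene_ids = [f"G{j:04d}" for j in range(p)]
    return values, sample_ids, gene_ids
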