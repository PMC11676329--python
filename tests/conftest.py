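import numpy as np
import pytest

import softpair as sp

TINY = dict(
    n_species=3,
    species_size=4,
    length_a=10,
    length_b=10,
    alphabet_size=8,
    n_coupled=40,
    coupling=0.95,
)


@pytest.fixture
def tiny_coupled():
    """Strongly coupled 3-species instance small enough for exhaustive oracles."""
    cfg = sp.GeneratorConfig(**TINY, seed=7)
    pair, truth = sp.generate_coupled_pair(cfg)
    return pair, truth


@pytest.fixture
def tiny_onehot(tiny_coupled):
    pair, truth = tiny_coupled
    return sp.one_hot_encode(pair.a), sp.one_hot_encode(pair.b), pair, truth


def random_doubly_stochastic(rng: np.random.Generator, n: int, iters: int = 400):
    m = rng.random((n, n)) + 1e-3
    for _ in range(iters):
        m /= m.sum(axis=1, keepdims=True)
        m /= m.sum(axis=0, keepdims=True)
    return m


def random_hard(rng: np.random.Generator, partition: sp.SpeciesPartition):
    return sp.HardPermutation(
        blocks=tuple(rng.permutation(s) for s in partition.sizes),
        partition=partition,
    )


def random_onehot(rng: np.random.Generator, n: int, l: int, q: int) -> sp.OneHotTensor:
    idx = rng.integers(q, size=(n, l))
    data = np.zeros((n, l, q))
    data[np.arange(n)[:, None], np.arange(l)[None, :], idx] = 1.0
    return sp.OneHotTensor(data=data, alphabet=sp.sequence_io.PROTEIN_ALPHABET[:q])
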