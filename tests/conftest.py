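import numpy as np
import pytest

from mirefscan.dataset import InteractionStore, InteractionTriple
from mirefscan.similarity import SimilarityMatrix
from mirefscan.synthetic import SyntheticConfig, generate

SMALL_CONFIG = SyntheticConfig(
    n_mirnas=30, n_efs=12, n_diseases=6, n_mirna_blocks=3, n_ef_blocks=2, seed=1
)


@pytest.fixture(scope="session")
def small_data():
    """A small planted-block dataset shared across tests (read-only)."""
    return generate(SMALL_CONFIG)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_store(rng, n_mirnas=8, n_efs=6, n_diseases=4, p=0.3):
    """A random triple store over fixed small universes."""
    mirnas = tuple(f"mir-{i}" for i in range(n_mirnas))
    efs = tuple(f"ef-{j}" for j in range(n_efs))
    diseases = tuple(f"dis-{d}" for d in range(n_diseases))
    triples = {
        InteractionTriple(m, e, d)
        for m in mirnas
        for e in efs
        for d in diseases
        if rng.random() < p
    }
    if not triples:
        triples = {InteractionTriple(mirnas[0], efs[0], diseases[0])}
    return InteractionStore.from_triples(triples, mirnas=mirnas, efs=efs, diseases=diseases)


def random_similarity(rng, n, labels=None):
    """A random symmetric non-negative similarity matrix with unit diagonal."""
    A = rng.random((n, n))
    S = (A + A.T) / 2.0
    np.fill_diagonal(S, 1.0)
    labels = labels if labels is not None else tuple(f"x{i}" for i in range(n))
    return SimilarityMatrix(tuple(labels), S)
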