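"""Similarity loading, shared-neighbor counts, normalization, integration."""

import itertools

import numpy as np
import pytest

from mirefscan.dataset import InteractionStore, InteractionTriple
from mirefscan.errors import AlignmentError, DataError, SchemaError
from mirefscan.similarity import (
    SimilarityMatrix,
    integrate_ef_similarity,
    integrate_mirna_similarity,
    integrated_similarities,
    load_similarity_matrix,
    normalize_similarity,
    shared_neighbor_counts,
    write_similarity_matrix,
)

from conftest import random_similarity, random_store


def test_round_trip(tmp_path, rng):
    sim = random_similarity(rng, 5)
    path = tmp_path / "sim.tsv"
    write_similarity_matrix(sim, path)
    loaded = load_similarity_matrix(path)
    assert loaded.labels == sim.labels
    np.testing.assert_allclose(loaded.values, sim.values, rtol=1e-11)
    # writing again reproduces the file bit for bit
    path2 = tmp_path / "sim2.tsv"
    write_similarity_matrix(loaded, path2)
    assert path.read_text() == path2.read_text()


def test_load_exact_2x2(tmp_path):
    path = tmp_path / "s.tsv"
    path.write_text("\te1\te2\ne1\t1\t0.3\ne2\t0.3\t1\n")
    sim = load_similarity_matrix(path)
    assert sim.labels == ("e1", "e2")
    np.testing.assert_array_equal(sim.values, [[1, 0.3], [0.3, 1]])


def test_load_pads_missing_entities(tmp_path):
    path = tmp_path / "s.tsv"
    path.write_text("\te1\ne1\t1\n")
    sim = load_similarity_matrix(path, expected_labels=("e1", "e2"))
    np.testing.assert_array_equal(sim.values, [[1, 0], [0, 1]])


@pytest.mark.parametrize(
    "content, err",
    [
        ("\te1\te2\ne1\t1\t0.3\n", SchemaError),  # not square
        ("\te1\te2\ne1\t1\t0.9\ne2\t0.3\t1\n", DataError),  # asymmetric
        ("\te1\te2\ne1\t1\t-0.3\ne2\t-0.3\t1\n", DataError),  # negative
    ],
)
def test_load_rejects_bad_tables(tmp_path, content, err):
    path = tmp_path / "bad.tsv"
    path.write_text(content)
    with pytest.raises(err):
        load_similarity_matrix(path)


def test_shared_neighbors_one_common_ef():
    store = InteractionStore.from_triples(
        [
            InteractionTriple("m1", "e1", "d1"),
            InteractionTriple("m1", "e2", "d1"),
            InteractionTriple("m2", "e2", "d1"),
            InteractionTriple("m2", "e3", "d1"),
        ]
    )
    sim = shared_neighbor_counts(store, "mirna", "ef")
    i, j = sim.index_of("m1"), sim.index_of("m2")
    assert sim.values[i, j] == 1
    assert sim.values[i, i] == 2 and sim.values[j, j] == 2


def test_shared_neighbors_identical_sets():
    efs = [f"e{k}" for k in range(4)]
    triples = [InteractionTriple(m, e, "d1") for m in ("m1", "m2") for e in efs]
    sim = shared_neighbor_counts(InteractionStore.from_triples(triples), "mirna", "ef")
    assert sim.values[0, 1] == len(efs)


def test_shared_neighbors_brute_force(rng):
    """All four network matrices match exhaustive set intersections."""
    store = random_store(rng, n_mirnas=8, n_efs=6, n_diseases=4)
    for entity, neighbor in [("mirna", "ef"), ("mirna", "disease"), ("ef", "mirna"), ("ef", "disease")]:
        sim = shared_neighbor_counts(store, entity, neighbor)
        labels = store.mirnas if entity == "mirna" else store.efs
        sets = {
            l: {getattr(t, neighbor) for t in store.triples if getattr(t, entity) == l}
            for l in labels
        }
        for a, b in itertools.product(labels, repeat=2):
            expected = len(sets[a] & sets[b]) if a != b else len(sets[a])
            assert sim.values[sim.index_of(a), sim.index_of(b)] == expected
        # intersections are bounded by the set sizes
        diag = np.diag(sim.values)
        assert np.all(sim.values <= np.minimum.outer(diag, diag) + 1e-12)


def test_shared_neighbors_usage_error(rng):
    with pytest.raises(ValueError):
        shared_neighbor_counts(random_store(rng), "ef", "ef")


@pytest.mark.parametrize(
    "values, expected",
    [
        ([[2.0, 0.0], [0.0, 3.0]], [[1.0, 0.0], [0.0, 1.0]]),
        ([[0.0, 1.0], [1.0, 0.0]], [[0.0, 1.0], [1.0, 0.0]]),
    ],
)
def test_normalize_small_cases(values, expected):
    sim = SimilarityMatrix(("a", "b"), np.array(values))
    np.testing.assert_allclose(normalize_similarity(sim).values, expected)


def test_normalize_elementwise_oracle(rng):
    values = rng.integers(0, 5, size=(6, 6)).astype(float)
    values = (values + values.T) / 2
    sim = SimilarityMatrix(tuple("abcdef"), values)
    out = normalize_similarity(sim).values
    r = values.sum(axis=1)
    for i in range(6):
        for j in range(6):
            expected = values[i, j] / np.sqrt(r[i] * r[j]) if r[i] > 0 and r[j] > 0 else 0.0
            assert out[i, j] == pytest.approx(expected, abs=1e-12)


def test_normalize_constant_row_sums(rng):
    # a circulant-like matrix: every row sums to the same constant
    values = np.full((4, 4), 0.5)
    np.fill_diagonal(values, 2.0)
    sim = SimilarityMatrix(tuple("abcd"), values)
    c = values.sum(axis=1)[0]
    np.testing.assert_allclose(normalize_similarity(sim).values, values / c)


def test_normalize_zero_row():
    sim = SimilarityMatrix(("a", "b"), np.array([[0.0, 0.0], [0.0, 1.0]]))
    out = normalize_similarity(sim).values
    assert out[0, 0] == 0 and out[0, 1] == 0 and out[1, 1] == 1


def test_integrate_ef_idempotent_mean(rng):
    X = random_similarity(rng, 4, labels=("e0", "e1", "e2", "e3"))
    out = integrate_ef_similarity(X, X, X, drug_efs=set(X.labels))
    off = ~np.eye(4, dtype=bool)
    np.testing.assert_allclose(out.values[off], X.values[off])
    np.testing.assert_allclose(np.diag(out.values), 1.0)


def test_integrate_ef_drug_mask():
    labels = ("e1", "e2")
    chem = SimilarityMatrix(labels, np.array([[1.0, 0.9], [0.9, 1.0]]))
    em = SimilarityMatrix(labels, np.array([[1.0, 0.2], [0.2, 1.0]]))
    ed = SimilarityMatrix(labels, np.array([[1.0, 0.4], [0.4, 1.0]]))
    # e2 is not a drug: chemical term excluded, entry is the network mean
    out = integrate_ef_similarity(chem, em, ed, drug_efs={"e1"})
    assert out.values[0, 1] == pytest.approx(0.3)
    # both drugs: chemical term averaged in
    out = integrate_ef_similarity(chem, em, ed, drug_efs={"e1", "e2"})
    assert out.values[0, 1] == pytest.approx((0.9 + 0.2 + 0.4) / 3)
    # optional behavior: averaging the zero chemical term instead
    out = integrate_ef_similarity(chem, em, ed, drug_efs=set(), include_chem_for_nondrug=True)
    assert out.values[0, 1] == pytest.approx((0.9 + 0.2 + 0.4) / 3)


def test_integrate_ef_elementwise_oracle(rng):
    labels = tuple(f"e{k}" for k in range(5))
    chem, em, ed = (random_similarity(rng, 5, labels) for _ in range(3))
    drugs = {"e0", "e2", "e3"}
    out = integrate_ef_similarity(chem, em, ed, drugs)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                expected = 1.0
            elif a in drugs and b in drugs:
                expected = (chem.values[i, j] + em.values[i, j] + ed.values[i, j]) / 3
            else:
                expected = (em.values[i, j] + ed.values[i, j]) / 2
            assert out.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_integrate_mirna_elementwise_oracle(rng):
    labels = tuple(f"m{k}" for k in range(5))
    func, me, md = (random_similarity(rng, 5, labels) for _ in range(3))
    out = integrate_mirna_similarity(func, me, md)
    off = ~np.eye(5, dtype=bool)
    expected = (func.values + me.values + md.values) / 3
    np.testing.assert_allclose(out.values[off], expected[off], atol=1e-12)
    np.testing.assert_allclose(np.diag(out.values), 1.0)


def test_integrate_mirna_zero_functional():
    labels = ("m1", "m2")
    zero = SimilarityMatrix(labels, np.zeros((2, 2)))
    me = SimilarityMatrix(labels, np.array([[0.0, 0.3], [0.3, 0.0]]))
    md = SimilarityMatrix(labels, np.array([[0.0, 0.6], [0.6, 0.0]]))
    out = integrate_mirna_similarity(zero, me, md)
    assert out.values[0, 1] == pytest.approx(0.3)


def test_integrate_label_mismatch(rng):
    a = random_similarity(rng, 3, labels=("x", "y", "z"))
    b = random_similarity(rng, 3, labels=("x", "z", "y"))
    with pytest.raises(AlignmentError):
        integrate_mirna_similarity(a, b, b)


def test_permutation_equivariance(rng):
    """Relabeling entities permutes every similarity output consistently."""
    store = random_store(rng, n_mirnas=6, n_efs=5, n_diseases=3)
    sim = shared_neighbor_counts(store, "mirna", "ef")
    norm = normalize_similarity(sim)
    perm = rng.permutation(len(store.mirnas))
    # same store, universes declared in permuted order
    store_p = InteractionStore.from_triples(
        store.triples,
        mirnas=tuple(store.mirnas[i] for i in perm),
        efs=store.efs,
        diseases=store.diseases,
    )
    norm_p = normalize_similarity(shared_neighbor_counts(store_p, "mirna", "ef"))
    np.testing.assert_allclose(norm.permute(perm).values, norm_p.values, atol=1e-12)
    assert norm.permute(perm).labels == norm_p.labels


def test_integrated_pipeline_invariants(small_data):
    sim_m, sim_e = integrated_similarities(small_data.store, small_data.chem, small_data.func)
    for sim in (sim_m, sim_e):
        assert np.max(np.abs(sim.values - sim.values.T)) <= 1e-10
        assert np.all(sim.values >= 0)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
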