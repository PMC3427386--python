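"""Similarity matrices over miRNAs and environmental factors.

Four sources of pairwise similarity feed the classifier:

* chemical-structure similarity between drug EFs (precomputed, e.g. a
  SIMCOMP common-substructure ratio), zero for any pair that is not two
  drugs;
* miRNA functional similarity (precomputed, e.g. MISIM scores);
* network-based similarity — the number of interaction partners (miRNAs,
  EFs, or diseases) two entities share in the triple network;
* the integrated matrices: equal-weight means of the precomputed source
  with the degree-normalized network sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import InteractionStore
from .errors import AlignmentError, DataError, SchemaError

SYMMETRY_TOL = 1e-10
#: asymmetry beyond this in an input file is treated as corrupt data
LOAD_ASYMMETRY_TOL = 1e-6


@dataclass(frozen=True)
class SimilarityMatrix:
    """A labeled, symmetric, non-negative square matrix.

    ``kind`` records provenance: ``"chemical"``, ``"functional"``,
    ``"network"``, ``"normalized-network"`` or ``"integrated"`` (plus
    ``"generic"`` for ad-hoc matrices).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise SchemaError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise SchemaError("duplicate labels in similarity matrix")
        if np.any(values < 0):
            raise DataError("negative similarity entries")
        if np.max(np.abs(values - values.T), initial=0.0) > SYMMETRY_TOL:
            raise DataError(f"matrix asymmetric beyond {SYMMETRY_TOL}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def reindex(self, labels: Sequence[str], fill_diagonal: float = 1.0) -> "SimilarityMatrix":
        """Restrict/expand to ``labels``; absent entities get zero
        off-diagonal similarity and ``fill_diagonal`` self-similarity."""
        labels = tuple(labels)
        pos = {l: i for i, l in enumerate(self.labels)}
        out = np.zeros((len(labels), len(labels)))
        present = [i for i, l in enumerate(labels) if l in pos]
        src = [pos[labels[i]] for i in present]
        out[np.ix_(present, present)] = self.values[np.ix_(src, src)]
        missing = [i for i, l in enumerate(labels) if l not in pos]
        for i in missing:
            out[i, i] = fill_diagonal
        return SimilarityMatrix(labels, out, self.kind)

    def permute(self, order: Sequence[int]) -> "SimilarityMatrix":
        order = list(order)
        return SimilarityMatrix(
            tuple(self.labels[i] for i in order), self.values[np.ix_(order, order)], self.kind
        )


def load_similarity_matrix(
    path: str | Path,
    expected_labels: Sequence[str] | None = None,
    kind: str = "generic",
    sep: str | None = None,
) -> SimilarityMatrix:
    """Read a labeled square similarity table.

    The first column holds row labels and the header the column labels.
    Mild asymmetry (≤ 1e-6, e.g. from rounding in the source) is repaired
    by averaging ``(S + Sᵀ)/2``; anything larger is an error.  When
    ``expected_labels`` is given, the matrix is aligned to it: entities
    missing from the file get zero rows/columns with self-similarity 1.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SchemaError(f"{path}: table is {df.shape[0]}×{df.shape[1]}, not square")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        if sorted(rows) != sorted(cols):
            raise SchemaError(f"{path}: row and column labels differ")
        df = df.loc[rows, rows]
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataError(f"{path}: negative similarity entries")
    asym = float(np.max(np.abs(values - values.T), initial=0.0))
    if asym > LOAD_ASYMMETRY_TOL:
        raise DataError(f"{path}: asymmetry {asym:.3g} exceeds {LOAD_ASYMMETRY_TOL}")
    values = (values + values.T) / 2.0
    sim = SimilarityMatrix(tuple(rows), values, kind)
    if expected_labels is not None:
        sim = sim.reindex(expected_labels)
    return sim


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a labeled square table; 12 significant digits round-trips."""
    sim.to_frame().to_csv(Path(path), sep=sep, float_format="%.12g")


def _incidence(store: InteractionStore, rows: str, cols: str) -> np.ndarray:
    """Binary co-occurrence matrix between two entity kinds of the store."""
    universes = {"mirna": store.mirnas, "ef": store.efs, "disease": store.diseases}
    r_index = {x: i for i, x in enumerate(universes[rows])}
    c_index = {x: j for j, x in enumerate(universes[cols])}
    B = np.zeros((len(r_index), len(c_index)))
    for t in store.triples:
        B[r_index[getattr(t, rows)], c_index[getattr(t, cols)]] = 1.0
    return B


def shared_neighbor_counts(
    store: InteractionStore, entity_kind: str, neighbor_kind: str
) -> SimilarityMatrix:
    """Count-of-shared-partners similarity from the triple network.

    Entry (i, j) is the number of ``neighbor_kind`` entities co-occurring
    (in any triple) with both entity i and entity j; the diagonal is the
    neighbor-set size |N(i)|.  With entity=ef this yields the shared-miRNA
    and shared-disease EF similarities, with entity=mirna the shared-EF
    and shared-disease miRNA similarities.
    """
    if entity_kind not in ("mirna", "ef") or neighbor_kind not in ("mirna", "ef", "disease"):
        raise ValueError("entity_kind must be mirna/ef, neighbor_kind mirna/ef/disease")
    if entity_kind == neighbor_kind:
        raise ValueError("entity_kind and neighbor_kind must differ")
    B = _incidence(store, entity_kind, neighbor_kind)
    labels = store.mirnas if entity_kind == "mirna" else store.efs
    return SimilarityMatrix(labels, B @ B.T, "network")


def normalize_similarity(S: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric degree normalization D^(−1/2) S D^(−1/2).

    Entry (i, j) becomes s_ij / sqrt(r_i r_j) with r_i the row sum of S;
    entities with zero degree keep zero rows (0/0 := 0).
    """
    r = S.values.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(r > 0, 1.0 / np.sqrt(np.where(r > 0, r, 1.0)), 0.0)
    out = S.values * np.outer(inv_sqrt, inv_sqrt)
    out = (out + out.T) / 2.0  # guard against floating-point drift
    return SimilarityMatrix(S.labels, out, "normalized-network")


def _check_aligned(mats: Sequence[SimilarityMatrix]) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise AlignmentError("similarity matrices have different label orderings")


def integrate_ef_similarity(
    chem: SimilarityMatrix,
    net_em_norm: SimilarityMatrix,
    net_ed_norm: SimilarityMatrix,
    drug_efs: Sequence[str] | frozenset[str],
    include_chem_for_nondrug: bool = False,
    weights: Sequence[float] | None = None,
) -> SimilarityMatrix:
    """Integrated EF similarity: per-pair mean of the available sources.

    Chemical-structure similarity is only defined when both EFs are
    drugs; for such pairs the entry is the (weighted) mean of chemical,
    shared-miRNA and shared-disease similarity, otherwise the mean of the
    two network sources alone.  Set ``include_chem_for_nondrug`` to
    average the (zero) chemical term into non-drug pairs instead of
    excluding it.  The diagonal is forced to 1.
    """
    _check_aligned([chem, net_em_norm, net_ed_norm])
    w = np.asarray(weights if weights is not None else (1.0, 1.0, 1.0), dtype=float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be three non-negative numbers, not all zero")
    is_drug = np.array([l in set(drug_efs) for l in chem.labels])
    pair_drug = np.outer(is_drug, is_drug)
    with_chem = (w[0] * chem.values + w[1] * net_em_norm.values + w[2] * net_ed_norm.values) / w.sum()
    net_only = (w[1] * net_em_norm.values + w[2] * net_ed_norm.values) / (w[1] + w[2])
    mask = pair_drug | include_chem_for_nondrug
    out = np.where(mask, with_chem, net_only)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(chem.labels, out, "integrated")


def integrate_mirna_similarity(
    func: SimilarityMatrix,
    net_me_norm: SimilarityMatrix,
    net_md_norm: SimilarityMatrix,
    weights: Sequence[float] | None = None,
) -> SimilarityMatrix:
    """Integrated miRNA similarity: per-pair (weighted) mean of functional,
    shared-EF and shared-disease similarity; diagonal forced to 1."""
    _check_aligned([func, net_me_norm, net_md_norm])
    w = np.asarray(weights if weights is not None else (1.0, 1.0, 1.0), dtype=float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be three non-negative numbers, not all zero")
    out = (w[0] * func.values + w[1] * net_me_norm.values + w[2] * net_md_norm.values) / w.sum()
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(func.labels, out, "integrated")


def integrated_similarities(
    store: InteractionStore,
    chem: SimilarityMatrix,
    func: SimilarityMatrix,
    use_network: bool = True,
    include_chem_for_nondrug: bool = False,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Full similarity pipeline: (miRNA matrix, EF matrix) for a store.

    Aligns the precomputed matrices to the store's universes, computes the
    four shared-neighbor matrices from the current triples, normalizes
    them, and integrates.  With ``use_network=False`` the precomputed
    sources are returned alone (diagonal forced to 1) — the ablation in
    which network similarity is ignored.
    """
    chem = chem.reindex(store.efs)
    func = func.reindex(store.mirnas)
    if not use_network:
        ef_vals = chem.values.copy()
        np.fill_diagonal(ef_vals, 1.0)
        m_vals = func.values.copy()
        np.fill_diagonal(m_vals, 1.0)
        return (
            SimilarityMatrix(store.mirnas, m_vals, "integrated"),
            SimilarityMatrix(store.efs, ef_vals, "integrated"),
        )
    s_em = normalize_similarity(shared_neighbor_counts(store, "ef", "mirna"))
    s_ed = normalize_similarity(shared_neighbor_counts(store, "ef", "disease"))
    s_me = normalize_similarity(shared_neighbor_counts(store, "mirna", "ef"))
    s_md = normalize_similarity(shared_neighbor_counts(store, "mirna", "disease"))
    sim_e = integrate_ef_similarity(
        chem, s_em, s_ed, store.drug_efs, include_chem_for_nondrug=include_chem_for_nondrug
    )
    sim_m = integrate_mirna_similarity(func, s_me, s_md)
    return sim_m, sim_e
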