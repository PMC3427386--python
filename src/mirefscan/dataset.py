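"""Curated (miRNA, environmental factor, disease) interaction triples.

The gold-standard input is a table of experimentally supported triples: a
miRNA, an environmental factor (EF — a drug, radiation, virus, diet
component...), and the disease in whose context the interaction was
observed.  This module parses and normalizes such tables, stores them with
set semantics, and builds the per-disease binary label matrix consumed by
the semi-supervised classifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidNameError, NotFoundError, SchemaError

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")
# species prefixes occasionally present on miRNA identifiers
_MIRNA_PREFIX = re.compile(r"^hsa[-_]")

NA_DISEASE = "n/a"


def normalize_name(raw: str, kind: str = "ef") -> str:
    """Return the canonical form of an entity name.

    Trim, collapse internal whitespace, case-fold; miRNA ids additionally
    lose a leading ``hsa-``/``hsa_`` species prefix.  Idempotent.

    Parameters
    ----------
    raw : str
        The name as it appears in an input file.
    kind : {"mirna", "ef", "disease"}
        Entity kind; only miRNA names get the species-prefix rule.
    """
    if kind not in ("mirna", "ef", "disease"):
        raise ValueError(f"unknown entity kind {kind!r}")
    if not isinstance(raw, str) or not raw.strip():
        raise InvalidNameError(f"empty or non-string {kind} name: {raw!r}")
    name = _WS.sub(" ", raw.strip()).lower()
    if kind == "mirna":
        name = _MIRNA_PREFIX.sub("", name)
    return name


@dataclass(frozen=True, order=True)
class InteractionTriple:
    """One experimentally supported (miRNA, EF, disease) relationship."""

    mirna: str
    ef: str
    disease: str

    def __post_init__(self) -> None:
        for kind in ("mirna", "ef", "disease"):
            value = getattr(self, kind)
            if not value:
                raise InvalidNameError(f"empty {kind} id in triple")


@dataclass(frozen=True)
class InteractionStore:
    """Deduplicated triples plus the global entity universes.

    The universes are global across diseases: a label matrix built for one
    disease always spans every miRNA and EF in the store, because
    prediction must be able to score pairs never seen with that disease.
    ``drug_efs`` flags the subset of EFs that are drugs — the only pairs
    for which chemical-structure similarity is defined.
    """

    triples: frozenset[InteractionTriple]
    mirnas: tuple[str, ...]
    efs: tuple[str, ...]
    diseases: tuple[str, ...]
    drug_efs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        mirnas, efs, diseases = set(self.mirnas), set(self.efs), set(self.diseases)
        for t in self.triples:
            if t.mirna not in mirnas or t.ef not in efs or t.disease not in diseases:
                raise NotFoundError(f"triple {t} outside the declared universes")
        if not self.drug_efs <= efs:
            raise NotFoundError("drug_efs contains ids absent from the EF universe")

    @classmethod
    def from_triples(
        cls,
        triples: Iterable[InteractionTriple],
        drug_efs: Iterable[str] = (),
        mirnas: Sequence[str] | None = None,
        efs: Sequence[str] | None = None,
        diseases: Sequence[str] | None = None,
    ) -> "InteractionStore":
        """Build a store; universes default to the sorted distinct ids."""
        tset = frozenset(triples)
        return cls(
            triples=tset,
            mirnas=tuple(sorted({t.mirna for t in tset})) if mirnas is None else tuple(mirnas),
            efs=tuple(sorted({t.ef for t in tset})) if efs is None else tuple(efs),
            diseases=tuple(sorted({t.disease for t in tset})) if diseases is None else tuple(diseases),
            drug_efs=frozenset(drug_efs),
        )

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def records(self) -> list[InteractionTriple]:
        """The triples in a deterministic (sorted) order."""
        return sorted(self.triples)

    def triples_for_disease(self, disease: str) -> list[InteractionTriple]:
        return sorted(t for t in self.triples if t.disease == disease)

    def remove(self, triple: InteractionTriple) -> "InteractionStore":
        """A copy without ``triple`` but with the universes unchanged.

        Used by leave-one-out cross validation, where the held-out
        interaction must stay scoreable.
        """
        if triple not in self.triples:
            raise NotFoundError(f"{triple} not in store")
        return InteractionStore(
            triples=self.triples - {triple},
            mirnas=self.mirnas,
            efs=self.efs,
            diseases=self.diseases,
            drug_efs=self.drug_efs,
        )


def load_triples(
    path: str | Path,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
    drug_annotations: str | Path | None = None,
) -> InteractionStore:
    """Read a delimited table of triples into an :class:`InteractionStore`.

    Rows whose disease normalizes to ``"n/a"`` are dropped (entries with
    no recorded phenotype), names are normalized, and exact duplicate
    triples are collapsed.

    Parameters
    ----------
    path : path
        TSV/CSV file with header columns ``mirna``, ``ef``, ``disease``
        (remappable through ``columns``).
    sep : str, optional
        Field separator; inferred from the extension when omitted
        (``.csv`` → comma, otherwise tab).
    columns : mapping, optional
        Maps the canonical keys ``mirna``/``ef``/``disease`` to the
        actual column names in the file.
    drug_annotations : path, optional
        Two-column table ``ef``, ``is_drug`` flagging the drug subset of
        EFs; EFs without an annotation are treated as non-drugs.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    # keep_default_na: "n/a" is a meaningful phenotype placeholder, not a NaN
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = {"mirna": "mirna", "ef": "ef", "disease": "disease"}
    if columns:
        colmap.update(columns)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    triples: set[InteractionTriple] = set()
    n_rows = 0
    for _, row in df.iterrows():
        n_rows += 1
        disease = normalize_name(row[colmap["disease"]], "disease")
        if disease == NA_DISEASE:
            continue
        triples.add(
            InteractionTriple(
                mirna=normalize_name(row[colmap["mirna"]], "mirna"),
                ef=normalize_name(row[colmap["ef"]], "ef"),
                disease=disease,
            )
        )
    if len(triples) < n_rows:
        logger.info("%s: collapsed %d rows into %d distinct triples", path, n_rows, len(triples))

    drugs: set[str] = set()
    if drug_annotations is not None:
        ann = pd.read_csv(Path(drug_annotations), sep=sep, dtype=str, keep_default_na=False)
        if "ef" not in ann.columns or "is_drug" not in ann.columns:
            raise SchemaError(f"{drug_annotations}: expected columns 'ef' and 'is_drug'")
        efs_in_store = {t.ef for t in triples}
        for _, row in ann.iterrows():
            if str(row["is_drug"]).strip().lower() in ("1", "true", "yes"):
                ef = normalize_name(row["ef"], "ef")
                if ef in efs_in_store:
                    drugs.add(ef)
    return InteractionStore.from_triples(triples, drug_efs=drugs)


@dataclass(frozen=True)
class LabelMatrix:
    """Binary miRNA × EF label matrix for one disease (matrix ``A``/``Y``)."""

    disease: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels), columns=list(self.col_labels))


def build_label_matrix(store: InteractionStore, disease: str) -> LabelMatrix:
    """The |M| × |E| binary matrix with 1 at this disease's known pairs.

    Spans the *global* universes; a disease whose triples were all removed
    (as can happen during cross validation) yields an all-zero matrix.
    """
    if disease not in store.diseases:
        raise NotFoundError(f"unknown disease {disease!r}")
    m_index = {m: i for i, m in enumerate(store.mirnas)}
    e_index = {e: j for j, e in enumerate(store.efs)}
    values = np.zeros((len(store.mirnas), len(store.efs)), dtype=float)
    for t in store.triples:
        if t.disease == disease:
            values[m_index[t.mirna], e_index[t.ef]] = 1.0
    return LabelMatrix(disease, store.mirnas, store.efs, values)


def dataset_summary(store: InteractionStore) -> dict:
    """Descriptive statistics of a store.

    Returns counts of triples and entities, the mean number of
    interactions per disease (unrounded and rounded to 2 decimals), and a
    histogram mapping k → number of diseases with exactly k triples.
    """
    per_disease = {d: 0 for d in store.diseases}
    for t in store.triples:
        per_disease[t.disease] += 1
    counts = list(per_disease.values())
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    n_dis = len(store.diseases)
    mean = store.n_triples / n_dis if n_dis else None
    return {
        "n_triples": store.n_triples,
        "n_mirnas": len(store.mirnas),
        "n_efs": len(store.efs),
        "n_diseases": n_dis,
        "mean_interactions_per_disease": mean,
        "mean_interactions_per_disease_2dp": round(mean, 2) if mean is not None else None,
        "interactions_per_disease_histogram": dict(sorted(hist.items())),
    }
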