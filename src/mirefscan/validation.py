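"""Statistical validation of the "similar nature" assumption.

The classifier rests on the observation that miRNA pairs interacting
with more similar EFs tend to be more similar themselves (and vice
versa).  Two experiments probe this on the interaction records:

1. over all unordered pairs of interaction records, the miRNA-pair and
   EF-pair similarities form two aligned vectors whose Spearman
   correlation measures the association;
2. miRNA pairs are filtered by the similarity of their interacting EF
   *sets* (maximum cross-pair similarity) at increasing cutoffs, and the
   distribution of the selected miRNA similarities is summarized — it
   should shift upward with the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import InteractionStore
from .errors import CoverageError, UndefinedCorrelationError
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class PairedSimilarityVectors:
    """Aligned miRNA-pair and EF-pair similarity vectors.

    Both vectors have length C(n, 2) over the n interaction records and
    are indexed by the same unordered record pairs.
    """

    sim_m: np.ndarray
    sim_e: np.ndarray
    n_interactions: int

    def __post_init__(self) -> None:
        expected = self.n_interactions * (self.n_interactions - 1) // 2
        if len(self.sim_m) != expected or len(self.sim_e) != expected:
            raise ValueError(f"vectors must have length C(n,2) = {expected}")


def pairwise_similarity_vectors(
    store: InteractionStore,
    sim_mirna: SimilarityMatrix,
    sim_ef: SimilarityMatrix,
) -> PairedSimilarityVectors:
    """Similarity vectors over all unordered pairs of interaction records.

    Records are the store's triples, enumerated globally across diseases
    in sorted order.  For a record pair ((m_a, e_a), (m_b, e_b)) the
    entries are (sim_mirna[m_a, m_b], sim_ef[e_a, e_b]); records sharing
    a miRNA or EF use self-similarity 1.
    """
    records = store.records()
    m_pos = {l: i for i, l in enumerate(sim_mirna.labels)}
    e_pos = {l: i for i, l in enumerate(sim_ef.labels)}
    try:
        mi = np.array([m_pos[t.mirna] for t in records])
        ei = np.array([e_pos[t.ef] for t in records])
    except KeyError as exc:
        raise CoverageError(f"entity {exc} missing from a similarity matrix") from exc
    a, b = np.triu_indices(len(records), k=1)
    vm = sim_mirna.values[mi[a], mi[b]]
    ve = sim_ef.values[ei[a], ei[b]]
    vm = np.where(mi[a] == mi[b], 1.0, vm)
    ve = np.where(ei[a] == ei[b], 1.0, ve)
    return PairedSimilarityVectors(vm, ve, len(records))


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided asymptotic p-value.

    Midrank ties; the p-value uses the t approximation (an exact
    permutation test is infeasible at the vector lengths involved).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def _neighbor_sets(store: InteractionStore, mode: str) -> dict[str, np.ndarray]:
    """Interacting-partner index sets: EF indices per miRNA (mode=mirna)
    or miRNA indices per EF (mode=ef)."""
    e_pos = {l: j for j, l in enumerate(store.efs)}
    m_pos = {l: i for i, l in enumerate(store.mirnas)}
    sets: dict[str, set[int]] = {}
    for t in store.triples:
        if mode == "mirna":
            sets.setdefault(t.mirna, set()).add(e_pos[t.ef])
        else:
            sets.setdefault(t.ef, set()).add(m_pos[t.mirna])
    return {k: np.fromiter(sorted(v), dtype=int) for k, v in sets.items()}


def cutoff_selection(
    store: InteractionStore,
    sim_mirna: SimilarityMatrix,
    sim_ef: SimilarityMatrix,
    cutoffs: Sequence[float],
    mode: str = "mirna",
    strict: bool = True,
) -> dict[float, np.ndarray]:
    """Entity-pair similarities selected by partner-set similarity cutoff.

    With ``mode="mirna"``: for every unordered miRNA pair, the similarity
    of their interacting EF sets is the maximum similarity over all cross
    pairs; if it exceeds the cutoff, the miRNA pair's own similarity is
    selected.  ``mode="ef"`` is the symmetric experiment.  Comparison is
    strict (>) by default.

    Returns a map cutoff → array of selected similarities (empty store →
    empty arrays).
    """
    if mode not in ("mirna", "ef"):
        raise ValueError("mode must be 'mirna' or 'ef'")
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    own_sim = sim_mirna if mode == "mirna" else sim_ef
    partner_sim = sim_ef if mode == "mirna" else sim_mirna
    entity_labels = store.mirnas if mode == "mirna" else store.efs
    pos = {l: i for i, l in enumerate(own_sim.labels)}
    sets = _neighbor_sets(store, mode)
    connected = [l for l in entity_labels if l in sets]
    if any(l not in pos for l in connected):
        raise CoverageError("entity missing from the similarity matrix")

    pair_own: list[float] = []
    pair_set_sim: list[float] = []
    P = partner_sim.values
    for i, la in enumerate(connected):
        na = sets[la]
        for lb in connected[i + 1 :]:
            nb = sets[lb]
            pair_set_sim.append(float(P[np.ix_(na, nb)].max()))
            pair_own.append(float(own_sim.values[pos[la], pos[lb]]))
    own_arr = np.asarray(pair_own)
    set_arr = np.asarray(pair_set_sim)
    cmp = np.greater if strict else np.greater_equal
    return {float(c): own_arr[cmp(set_arr, c)] for c in cutoffs}


def selection_summary(selections: dict[float, np.ndarray]) -> pd.DataFrame:
    """Box-plot style summary per cutoff: count, quartiles, median."""
    rows = []
    for cutoff, values in selections.items():
        if values.size:
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            rows.append((cutoff, values.size, q1, med, q3))
        else:
            rows.append((cutoff, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["cutoff", "n_selected", "q1", "median", "q3"])
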