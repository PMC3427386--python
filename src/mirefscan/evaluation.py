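"""Leave-one-out cross validation and parameter sweeps.

Each known interaction of a disease is withheld in turn; the
network-based similarities are recomputed on the remaining triples (so no
information from the held-out interaction leaks into the similarity
graph), the classifier is refit, and the rank of the held-out pair among
all unknown candidates of that disease is recorded.  Per-fold AUC is the
normalized rank; the overall AUC is the mean over folds, with the mean of
per-disease AUCs also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import InteractionStore, InteractionTriple, build_label_matrix
from .errors import UndefinedResultError, UnsupportedDiseaseError
from .laprls import LapRLSConfig, LapRLSScan
from .similarity import SimilarityMatrix, integrated_similarities

#: ablation variants: (use network similarity, lambda override or None)
VARIANTS: dict[str, tuple[bool, float | None]] = {
    "full": (True, None),
    "combined_no_network": (False, None),
    "no_network_similarity": (False, None),
    "mirna_space_only": (True, 1.0),
    "ef_space_only": (True, 0.0),
}


@dataclass(frozen=True)
class FoldRecord:
    """Outcome of one leave-one-out fold."""

    disease: str
    mirna: str
    ef: str
    rank: float
    n_candidates: int


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one method variant."""

    folds: tuple[FoldRecord, ...]
    per_disease_auc: dict[str, float]
    overall_auc: float
    macro_auc: float  # mean of per-disease AUCs (alternative pooling)
    variant: str = "full"

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.disease, f.mirna, f.ef, f.rank, f.n_candidates) for f in self.folds],
            columns=["disease", "mirna", "ef", "rank", "n_candidates"],
        )


def fold_auc(rank: float, n_candidates: int) -> float:
    """AUC of a single fold: the fraction of negatives ranked below the
    held-out positive, (n − rank) / (n − 1)."""
    if n_candidates < 2:
        raise UndefinedResultError("fold AUC undefined for fewer than two candidates")
    return (n_candidates - rank) / (n_candidates - 1)


def roc_auc_from_folds(folds: Iterable[tuple[float, int]]) -> float:
    """Mean per-fold AUC over (rank, n_candidates) pairs.

    Ranks may be fractional (midrank ties).  Folds with a single
    candidate carry no ranking information and are dropped with a
    warning.
    """
    contributions = []
    for rank, n in folds:
        if not 1 <= rank <= n:
            raise ValueError(f"rank {rank} outside [1, {n}]")
        if n < 2:
            warnings.warn("dropping single-candidate fold from AUC")
            continue
        contributions.append(fold_auc(rank, n))
    if not contributions:
        raise UndefinedResultError("no folds with at least two candidates")
    return float(np.mean(contributions))


def _midrank(target_score: float, candidate_scores: np.ndarray) -> float:
    """1-based rank of the target among candidates (target included),
    averaging over ties."""
    greater = int(np.sum(candidate_scores > target_score))
    equal = int(np.sum(candidate_scores == target_score))  # includes the target itself
    return greater + (equal + 1) / 2.0


def loocv(
    store: InteractionStore,
    chem: SimilarityMatrix,
    func: SimilarityMatrix,
    config: LapRLSConfig | None = None,
    variant: str = "full",
    diseases: Sequence[str] | None = None,
) -> CVResult:
    """Leave-one-out cross validation with per-fold similarity recalculation.

    Only diseases with at least two known interactions are eligible (a
    single-interaction disease leaves no training seed).  For every fold
    the four shared-neighbor matrices and the integrated similarities are
    rebuilt from the training triples.

    Parameters
    ----------
    store : InteractionStore
        Full gold-standard triples.
    chem, func : SimilarityMatrix
        Precomputed EF chemical and miRNA functional similarity.
    config : LapRLSConfig
        Classifier hyper-parameters (defaults: β=1, λ=0.5).
    variant : str
        ``full``, ``combined_no_network`` (precomputed similarities only),
        ``mirna_space_only`` (λ=1) or ``ef_space_only`` (λ=0).
    diseases : sequence, optional
        Restrict evaluation to these diseases.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    use_network, lam_override = VARIANTS[variant]
    config = config or LapRLSConfig()
    if lam_override is not None:
        config = LapRLSConfig(config.beta_m, config.beta_e, lam_override, config.ridge)

    counts: dict[str, int] = {}
    for t in store.triples:
        counts[t.disease] = counts.get(t.disease, 0) + 1
    pool = diseases if diseases is not None else store.diseases
    eligible = [d for d in pool if counts.get(d, 0) >= 2]
    if not eligible:
        raise UnsupportedDiseaseError("no disease has at least two known interactions")

    records: list[FoldRecord] = []
    for disease in eligible:
        for triple in store.triples_for_disease(disease):
            train = store.remove(triple)
            sim_m, sim_e = integrated_similarities(train, chem, func, use_network=use_network)
            Y = build_label_matrix(train, disease).values
            model = LapRLSScan.from_config(config).fit(sim_m, sim_e, Y)
            scores = model.scores_
            i = store.mirnas.index(triple.mirna)
            j = store.efs.index(triple.ef)
            candidate_scores = scores[Y == 0]  # includes the held-out pair
            rank = _midrank(scores[i, j], candidate_scores)
            records.append(FoldRecord(disease, triple.mirna, triple.ef, rank, candidate_scores.size))

    per_disease = {
        d: roc_auc_from_folds((f.rank, f.n_candidates) for f in records if f.disease == d)
        for d in eligible
    }
    overall = roc_auc_from_folds((f.rank, f.n_candidates) for f in records)
    macro = float(np.mean(list(per_disease.values())))
    return CVResult(tuple(records), per_disease, overall, macro, variant)


def parameter_sweep(
    store: InteractionStore,
    chem: SimilarityMatrix,
    func: SimilarityMatrix,
    beta_grid: Sequence[float],
    lambda_grid: Sequence[float] = (0.5,),
    beta_e_grid: Sequence[float] | None = None,
    ridge: float = 1e-8,
    variant: str = "full",
) -> pd.DataFrame:
    """LOOCV over a hyper-parameter grid.

    ``beta_grid`` sets β_M; β_E follows β_M unless ``beta_e_grid`` is
    given, in which case the full β_M × β_E product is evaluated.
    Returns a tidy table (beta_m, beta_e, lambda, auc), one LOOCV per
    row, deterministic given the inputs.
    """
    if not beta_grid or not lambda_grid:
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for beta_m in beta_grid:
        for beta_e in beta_e_grid if beta_e_grid is not None else [beta_m]:
            for lam in lambda_grid:
                config = LapRLSConfig(beta_m, beta_e, lam, ridge)
                result = loocv(store, chem, func, config, variant=variant)
                rows.append((beta_m, beta_e, lam, result.overall_auc))
    return pd.DataFrame(rows, columns=["beta_m", "beta_e", "lambda", "auc"])
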