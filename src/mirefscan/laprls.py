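"""Laplacian regularized least squares (LapRLS) link prediction.

For one disease, the known miRNA–EF interactions form a binary label
matrix Y (miRNAs × EFs).  A classifier is trained in each of the two
entity spaces: it should (1) reproduce the known labels and (2) be smooth
over the similarity graph, so that similar miRNAs (EFs) combined with the
same partner receive similar scores.  With S the integrated similarity
matrix and L = I − D^(−1/2) S D^(−1/2) its normalized Laplacian, the
closed-form minimizer of ``‖Y − F‖²_F + β tr(FᵀLF)`` over functions of the
form F = S·α is

    F = S (S + β L S + ridge·I)^(−1) Y

computed in the miRNA space on Y and in the EF space on Yᵀ.  The final
score matrix is the convex blend λ·F_M + (1−λ)·F_Eᵀ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .dataset import InteractionStore, build_label_matrix
from .errors import AlignmentError, ConfigError, DataError, NumericalError, UnsupportedDiseaseError
from .similarity import SimilarityMatrix

DEFAULT_RIDGE = 1e-8


@dataclass(frozen=True)
class LapRLSConfig:
    """Hyper-parameters of the two-space LapRLS classifier.

    beta_m, beta_e
        Non-negative trade-off between label fit and graph smoothness in
        the miRNA and EF space; 0 reduces to plain least squares (F = Y
        for nonsingular S).
    lambda_weight
        Weight of the miRNA-space scores in the final blend, in [0, 1];
        0.5 averages the two spaces.
    ridge
        Small diagonal regularizer for singular systems.
    """

    beta_m: float = 1.0
    beta_e: float = 1.0
    lambda_weight: float = 0.5
    ridge: float = DEFAULT_RIDGE

    def __post_init__(self) -> None:
        if self.beta_m < 0 or self.beta_e < 0:
            raise ConfigError("trade-off parameters must be non-negative")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ConfigError("lambda_weight must lie in [0, 1]")
        if self.ridge < 0:
            raise ConfigError("ridge must be non-negative")


def normalized_laplacian(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """L = I − D^(−1/2) S D^(−1/2) with D = diag(row sums of S).

    Zero-degree entities contribute an identity row (diagonal 1,
    off-diagonal 0).  L is symmetric positive semidefinite.
    """
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if np.any(values < 0):
        raise DataError("similarity matrix has negative entries")
    r = values.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(r > 0, 1.0 / np.sqrt(np.where(r > 0, r, 1.0)), 0.0)
    A = values * np.outer(inv_sqrt, inv_sqrt)
    L = np.eye(values.shape[0]) - A
    return (L + L.T) / 2.0


def laprls_solve(
    S: SimilarityMatrix | np.ndarray,
    Y: np.ndarray,
    beta: float,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Closed-form LapRLS solution F = S (S + β L S + ridge·I)^(−1) Y.

    Solved as a linear system (never an explicit inverse).  A singular
    system at ridge = 0 is retried once with the default ridge.
    """
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != values.shape[0]:
        raise AlignmentError(f"Y has {Y.shape[0]} rows but S is {values.shape[0]}×{values.shape[0]}")
    if beta < 0:
        raise ConfigError("beta must be non-negative")
    L = normalized_laplacian(values)
    A = values + beta * (L @ values)

    def _solve(reg: float) -> np.ndarray:
        return scipy.linalg.solve(A + reg * np.eye(A.shape[0]), Y)

    try:
        X = _solve(ridge)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
        if ridge > 0:
            raise NumericalError("LapRLS system singular despite ridge regularization")
        warnings.warn("singular LapRLS system at ridge=0; retrying with default ridge")
        try:
            X = _solve(DEFAULT_RIDGE)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError, ValueError) as exc:
            raise NumericalError("LapRLS system singular despite ridge regularization") from exc
    return values @ X


def combine_scores(F_m: np.ndarray, F_e: np.ndarray, lambda_weight: float) -> np.ndarray:
    """Blend the two space-specific score matrices.

    ``F_m`` is miRNA × EF; ``F_e`` comes from the EF-space classifier and
    is EF × miRNA, so it is transposed before the convex combination
    λ·F_M + (1−λ)·F_Eᵀ.
    """
    F_m = np.asarray(F_m, dtype=float)
    F_e = np.asarray(F_e, dtype=float)
    if F_e.T.shape != F_m.shape:
        raise AlignmentError(f"shape mismatch: F_m {F_m.shape} vs F_e {F_e.shape}")
    if not 0.0 <= lambda_weight <= 1.0:
        raise ConfigError("lambda_weight must lie in [0, 1]")
    return lambda_weight * F_m + (1.0 - lambda_weight) * F_e.T


class LapRLSScan(BaseEstimator):
    """Two-space LapRLS scorer for disease-specific miRNA–EF pairs.

    Scikit-learn-style estimator: hyper-parameters are constructor
    arguments (``get_params``/``set_params`` work), fitting stores
    ``f_mirna_``, ``f_ef_`` and the blended ``scores_``.

    Parameters
    ----------
    beta_m, beta_e : float
        Smoothness trade-off in the miRNA and EF space.
    lambda_weight : float
        Weight of the miRNA space in the final blend.
    ridge : float
        Diagonal regularizer for the linear solves.
    """

    def __init__(
        self,
        beta_m: float = 1.0,
        beta_e: float = 1.0,
        lambda_weight: float = 0.5,
        ridge: float = DEFAULT_RIDGE,
    ):
        self.beta_m = beta_m
        self.beta_e = beta_e
        self.lambda_weight = lambda_weight
        self.ridge = ridge

    @classmethod
    def from_config(cls, config: LapRLSConfig) -> "LapRLSScan":
        return cls(config.beta_m, config.beta_e, config.lambda_weight, config.ridge)

    def fit(self, sim_mirna: SimilarityMatrix, sim_ef: SimilarityMatrix, Y: np.ndarray) -> "LapRLSScan":
        """Fit both space-specific classifiers on the label matrix Y.

        Parameters
        ----------
        sim_mirna, sim_ef : SimilarityMatrix
            Integrated similarity over miRNAs (rows of Y) and EFs
            (columns of Y).
        Y : ndarray of shape (n_mirnas, n_efs)
            Binary labels for one disease.
        """
        LapRLSConfig(self.beta_m, self.beta_e, self.lambda_weight, self.ridge)  # validate
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (sim_mirna.n, sim_ef.n):
            raise AlignmentError(
                f"Y shape {Y.shape} does not match similarities ({sim_mirna.n}, {sim_ef.n})"
            )
        self.row_labels_ = sim_mirna.labels
        self.col_labels_ = sim_ef.labels
        self.f_mirna_ = laprls_solve(sim_mirna, Y, self.beta_m, self.ridge)
        self.f_ef_ = laprls_solve(sim_ef, Y.T, self.beta_e, self.ridge)
        self.scores_ = combine_scores(self.f_mirna_, self.f_ef_, self.lambda_weight)
        if not np.all(np.isfinite(self.scores_)):
            raise NumericalError("non-finite scores after solving")
        return self

    def decision_function(self) -> np.ndarray:
        """The blended miRNA × EF score matrix F."""
        if not hasattr(self, "scores_"):
            raise NumericalError("estimator is not fitted")
        return self.scores_


def rank_candidates(
    scores: np.ndarray,
    Y: np.ndarray,
    row_labels: tuple[str, ...],
    col_labels: tuple[str, ...],
    top_k: int | None = None,
) -> list[tuple[str, str, float]]:
    """Candidate pairs (Y = 0) sorted by descending score.

    Ties are broken lexicographically on (miRNA, EF); known pairs are
    excluded.
    """
    rows, cols = np.nonzero(np.asarray(Y) == 0)
    entries = [(row_labels[i], col_labels[j], float(scores[i, j])) for i, j in zip(rows, cols)]
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return entries[:top_k] if top_k is not None else entries


def predict_disease(
    store: InteractionStore,
    sim_mirna: SimilarityMatrix,
    sim_ef: SimilarityMatrix,
    disease: str,
    config: LapRLSConfig | None = None,
    top_k: int | None = None,
) -> list[tuple[str, str, float]]:
    """Ranked novel-candidate list for one disease.

    Builds the label matrix, fits the two-space classifier, and returns
    unknown pairs sorted by descending blended score.  Diseases with no
    known interaction carry no seed labels and cannot be scored.
    """
    config = config or LapRLSConfig()
    Y = build_label_matrix(store, disease).values
    if Y.sum() == 0:
        raise UnsupportedDiseaseError(f"disease {disease!r} has no known miRNA-EF interaction")
    model = LapRLSScan.from_config(config).fit(sim_mirna, sim_ef, Y)
    return rank_candidates(model.scores_, Y, store.mirnas, store.efs, top_k)
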