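"""Synthetic interaction networks with planted block structure.

The generator emulates the statistical structure the method relies on:
miRNAs and EFs fall into functional blocks, similarity is high within a
block and low across blocks, and each disease draws its interactions
from one (miRNA-block, EF-block) combination — so similar miRNAs really
do interact with similar EFs.  A held-out fraction of the planted
positives serves as ground truth for end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .dataset import InteractionStore, InteractionTriple, build_label_matrix
from .errors import ConfigError
from .laprls import LapRLSConfig, LapRLSScan
from .similarity import SimilarityMatrix, integrated_similarities, write_similarity_matrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults give 200 miRNAs and 60 EFs in 4 × 3 blocks, 20 diseases,
    within-block similarity 0.8 against a 0.1 cross-block background,
    planted interactions at rate 0.15 inside each disease's block pair,
    and 20% of positives withheld as ground truth.
    """

    n_mirnas: int = 200
    n_efs: int = 60
    n_diseases: int = 20
    n_mirna_blocks: int = 4
    n_ef_blocks: int = 3
    within_block_sim: float = 0.8
    cross_block_sim: float = 0.1
    noise: float = 0.02
    interaction_rate: float = 0.15
    holdout_fraction: float = 0.2
    drug_fraction: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_efs, self.n_diseases) < 1:
            raise ConfigError("entity counts must be positive")
        if self.n_mirna_blocks > self.n_mirnas or self.n_ef_blocks > self.n_efs:
            raise ConfigError("more blocks than entities")
        if not (0 < self.within_block_sim <= 1 and 0 <= self.cross_block_sim < 1):
            raise ConfigError("block similarities outside their ranges")
        if self.within_block_sim < self.cross_block_sim:
            raise ConfigError("within-block similarity must not be below cross-block")
        if not 0 < self.interaction_rate < 1:
            raise ConfigError("interaction_rate must lie in (0, 1)")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction must lie in (0, 1)")
        if not 0 <= self.drug_fraction <= 1:
            raise ConfigError("drug_fraction must lie in [0, 1]")
        if self.noise < 0:
            raise ConfigError("noise must be non-negative")


class SyntheticData(NamedTuple):
    store: InteractionStore
    chem: SimilarityMatrix
    func: SimilarityMatrix
    holdout: list[InteractionTriple]
    mirna_blocks: np.ndarray
    ef_blocks: np.ndarray


def _block_assignment(n: int, k: int) -> np.ndarray:
    """Contiguous near-equal partition: entity i → block id."""
    out = np.zeros(n, dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(n), k)):
        out[chunk] = b
    return out


def _block_similarity(
    labels: tuple[str, ...],
    blocks: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    same = blocks[:, None] == blocks[None, :]
    base = np.where(same, config.within_block_sim, config.cross_block_sim)
    noise = rng.uniform(-config.noise, config.noise, size=base.shape)
    S = np.clip(base + (noise + noise.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(config: SyntheticConfig | None = None) -> SyntheticData:
    """Generate a triple store, similarity matrices, and a holdout set.

    Deterministic given ``config.seed``.  Each disease is assigned a
    (miRNA-block, EF-block) pair round-robin and its positive pairs are
    sampled inside that block pair at ``interaction_rate``.  Note that
    the planted interactions therefore carry block structure on their
    own: even with a flat similarity matrix, the shared-neighbor
    similarities computed from the training triples partially recover
    the blocks.  Chemical similarity is zeroed off-diagonal for any pair
    not consisting of two drugs, mirroring the structure of a
    structure-based drug similarity matrix.  At least one training
    triple is kept per disease so every disease stays scoreable.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    mirnas = tuple(f"mir-{i:04d}" for i in range(config.n_mirnas))
    efs = tuple(f"ef-{j:03d}" for j in range(config.n_efs))
    diseases = tuple(f"disease-{d:02d}" for d in range(config.n_diseases))

    m_blocks = _block_assignment(config.n_mirnas, config.n_mirna_blocks)
    e_blocks = _block_assignment(config.n_efs, config.n_ef_blocks)

    func = _block_similarity(mirnas, m_blocks, config, rng)
    ef_latent = _block_similarity(efs, e_blocks, config, rng)

    n_drugs = int(round(config.drug_fraction * config.n_efs))
    drug_idx = np.sort(rng.choice(config.n_efs, size=n_drugs, replace=False))
    drugs = frozenset(efs[j] for j in drug_idx)
    is_drug = np.zeros(config.n_efs, dtype=bool)
    is_drug[drug_idx] = True
    chem = np.where(np.outer(is_drug, is_drug), ef_latent, 0.0)
    np.fill_diagonal(chem, 1.0)

    training: list[InteractionTriple] = []
    holdout: list[InteractionTriple] = []
    for d, disease in enumerate(diseases):
        mb = d % config.n_mirna_blocks  # round-robin block assignment
        eb = d % config.n_ef_blocks
        mi = np.nonzero(m_blocks == mb)[0]
        ej = np.nonzero(e_blocks == eb)[0]
        mask = rng.random((mi.size, ej.size)) < config.interaction_rate
        pairs = [(mirnas[mi[a]], efs[ej[b]]) for a, b in zip(*np.nonzero(mask))]
        if not pairs:
            continue
        held = rng.random(len(pairs)) < config.holdout_fraction
        if held.all():
            held[0] = False
        for (m, e), h in zip(pairs, held):
            (holdout if h else training).append(InteractionTriple(m, e, disease))

    store = InteractionStore.from_triples(
        training, drug_efs=drugs, mirnas=mirnas, efs=efs, diseases=diseases
    )
    return SyntheticData(
        store,
        SimilarityMatrix(efs, chem, "chemical"),
        SimilarityMatrix(mirnas, func, "functional"),
        sorted(holdout),
        m_blocks,
        e_blocks,
    )


def recovery_auc(data: SyntheticData, config: LapRLSConfig | None = None) -> float:
    """Pooled AUC of held-out positives against all unknown candidates.

    Runs the full pipeline (network similarity recomputation, two-space
    classifier) per disease on the training store, scores every unknown
    pair, and labels it positive iff the corresponding triple was
    withheld.  An AUC near 1 means the planted structure was recovered.
    """
    if not data.holdout:
        raise ValueError("holdout set is empty")
    config = config or LapRLSConfig()
    sim_m, sim_e = integrated_similarities(data.store, data.chem, data.func)
    held = set(data.holdout)
    held_diseases = {t.disease for t in held}
    m_pos = {m: i for i, m in enumerate(data.store.mirnas)}
    e_pos = {e: j for j, e in enumerate(data.store.efs)}

    scores_all: list[np.ndarray] = []
    labels_all: list[np.ndarray] = []
    for disease in sorted(held_diseases):
        Y = build_label_matrix(data.store, disease).values
        if Y.sum() == 0:
            continue
        model = LapRLSScan.from_config(config).fit(sim_m, sim_e, Y)
        positive = np.zeros_like(Y, dtype=bool)
        for t in held:
            if t.disease == disease:
                positive[m_pos[t.mirna], e_pos[t.ef]] = True
        unknown = Y == 0
        scores_all.append(model.scores_[unknown])
        labels_all.append(positive[unknown])
    scores = np.concatenate(scores_all)
    labels = np.concatenate(labels_all)
    return float(roc_auc_score(labels, scores))


def write_synthetic(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write the generated inputs in the formats the loaders read.

    Produces ``triples.tsv``, ``ef_annotations.tsv``,
    ``chem_similarity.tsv``, ``func_similarity.tsv`` and
    ``holdout.tsv`` under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "triples": outdir / "triples.tsv",
        "ef_annotations": outdir / "ef_annotations.tsv",
        "chem": outdir / "chem_similarity.tsv",
        "func": outdir / "func_similarity.tsv",
        "holdout": outdir / "holdout.tsv",
    }
    pd.DataFrame(
        [(t.mirna, t.ef, t.disease) for t in data.store.records()],
        columns=["mirna", "ef", "disease"],
    ).to_csv(paths["triples"], sep="\t", index=False)
    pd.DataFrame(
        [(e, int(e in data.store.drug_efs)) for e in data.store.efs],
        columns=["ef", "is_drug"],
    ).to_csv(paths["ef_annotations"], sep="\t", index=False)
    write_similarity_matrix(data.chem, paths["chem"])
    write_similarity_matrix(data.func, paths["func"])
    pd.DataFrame(
        [(t.mirna, t.ef, t.disease) for t in data.holdout],
        columns=["mirna", "ef", "disease"],
    ).to_csv(paths["holdout"], sep="\t", index=False)
    return paths
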