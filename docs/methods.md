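# Methods

## Model

`mirefscan` treats disease-specific miRNA–EF interaction prediction as
transductive link prediction on a bipartite network. For a disease with
label matrix Y (miRNAs × EFs, 1 at experimentally supported pairs, 0
elsewhere — the zeros are *unlabeled*, not negative), a classifier F is
sought that (i) reproduces the known labels and (ii) is smooth over each
entity-similarity graph, so that similar miRNAs (EFs) paired with the
same partner obtain similar scores. Both requirements are encoded by the
Laplacian regularized least-squares (LapRLS) cost

    J(F) = ‖Y − F‖²_F + β · tr(Fᵀ L F),

minimized over functions of the form F = S·α, where S is the integrated
similarity matrix of the space and L its normalized Laplacian. The
resulting closed form is

    F = S (S + β L S + ridge·I)^(−1) Y,

evaluated once in the miRNA space (on Y) and once in the EF space (on
Yᵀ). The linear system is solved directly (LAPACK `solve`), never by
explicit inversion. Final scores are the convex blend
λ·F_M + (1−λ)·F_Eᵀ. The model is transductive: there is no held-out
"predict" step — fitting scores every pair in the universes at once.

### Assumptions

* Similar miRNAs interact with similar EFs in the context of a disease
  (verified empirically by the `validation` module; see below).
* A disease must have at least one known interaction: the method has no
  disease–disease similarity channel, so a label-free disease gives the
  zero matrix and an uninformative F.
* Unlabeled pairs are treated as soft negatives through the least-squares
  fit — appropriate because true negatives are not observable.

## Similarity construction

Two precomputed sources are consumed as labeled square tables: a
chemical-structure similarity over EFs (meaningful only between drug
pairs; all other entries are zero by construction) and a functional
similarity over miRNAs. Four network-based sources are computed from the
triples themselves: entry (i, j) of a shared-neighbor matrix is
|N(i) ∩ N(j)|, the number of partners (EFs, miRNAs, or diseases) the two
entities co-occur with; the diagonal is |N(i)|, so the intersection bound
entry ≤ min(diag_i, diag_j) holds. Counts are scaled by the symmetric
degree normalization D^(−1/2) S D^(−1/2) (zero-degree rows map to zero:
0/0 := 0), which keeps the matrix symmetric — required by the Laplacian
downstream. Integration is an equal-weight mean per pair, with the
diagonal then forced to 1 so that self-similarity is maximal and constant
for ranking. For EF pairs that are not both drugs, the undefined chemical
term is *excluded* from the mean (mean over the two network terms) rather
than averaged in as zero, which would systematically depress every
non-drug EF's similarity; averaging-in-zero remains available via
`include_chem_for_nondrug=True`. A weight vector is exposed for non-equal
combinations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β_M, β_E | 1.0 | smoothness trade-off per space; 0 reduces to F = Y for nonsingular S, large values flatten scores along the graph |
| λ | 0.5 | weight of the miRNA space in the final blend; 1 and 0 give the single-space ablations |
| ridge | 1e−8 | diagonal stabilizer; only material when S + βLS is singular (e.g. many isolated entities) |
| integration weights | equal | per-source weights of the similarity mean |

All are dimensionless. λ = 0.5 simply averages the two spaces, the
neutral choice when there is no reason to privilege either; cross-
validated LOOCV AUC is flat over a wide range of β and λ, so the defaults
are not critical.

## Evaluation protocol

Leave-one-out cross validation over every disease with at least two known
interactions (a singleton disease would leave no training seed). Per
fold, the held-out triple is removed and **all four network-based
similarity matrices are recomputed from the remaining triples**, so no
information from the test interaction leaks through the similarity graph;
the precomputed chemical/functional matrices are fold-independent inputs.
The held-out pair is ranked (midrank on ties) among all pairs unlabeled
for that disease in the training fold, plus itself. The per-fold AUC of a
single positive at rank r among n candidates is (n − r)/(n − 1) — the
fraction of negatives it outranks, identical to the Mann–Whitney
statistic. The pooling rule for the overall AUC is not uniquely
determined, so both views are computed: the mean over folds
(`overall_auc`, the headline number) and the mean of per-disease AUCs
(`macro_auc`). Single-candidate folds carry no ranking information and
are dropped with a warning.

Ablation variants: `combined_no_network` (precomputed similarities only —
with the alias `no_network_similarity`), `mirna_space_only` (λ = 1) and
`ef_space_only` (λ = 0). The λ-override variants are exactly equivalent
to running `full` with the corresponding λ, and the tests assert this.

## Assumption validation

Experiment 1: all C(n, 2) unordered pairs of the n interaction records
(globally across diseases — the only reading consistent with a vector
length of n(n−1)/2) yield two aligned vectors of miRNA-pair and EF-pair
integrated similarities; records sharing an entity use self-similarity 1.
Their Spearman correlation (midrank ties, two-sided asymptotic t p-value;
an exact permutation test is infeasible at ~3.7 × 10⁵ pairs) measures the
association. Experiment 2: for each miRNA pair, the similarity of their
interacting EF *sets* is the maximum similarity over cross pairs; pairs
whose set similarity exceeds a cutoff (strict `>` by default,
configurable) contribute their own similarity to that cutoff's
distribution, summarized by quartiles. Selection counts are
non-increasing in the cutoff by construction; on planted-block data the
selected-pair median rises with the cutoff.

## Synthetic data generator

The generator emulates the structure the method exploits: miRNAs and EFs
are partitioned into contiguous blocks; similarity is
`within_block_sim` (default 0.8) inside a block and `cross_block_sim`
(default 0.1) across, plus symmetric uniform noise of amplitude 0.02
(clipped to [0, 1], diagonal 1 — the noise breaks exact ties without
violating any matrix invariant). Each disease is assigned a
(miRNA-block, EF-block) pair round-robin, and its positive pairs are
sampled inside that block pair at `interaction_rate` (default 0.15);
defaults are 200 miRNAs and 60 EFs in 4 × 3 blocks with 20 diseases. A
`holdout_fraction` (default 0.2) of positives is withheld as ground
truth, with at least one training triple kept per disease. A random
`drug_fraction` (default 0.5) of EFs is flagged as drugs, and chemical
similarity is zeroed for any non-drug pair.

What the generator does *not* emulate: the heavy-tailed degree
distribution of real curated data (real diseases range from 1 to dozens
of interactions; generated diseases are roughly balanced), name
normalization noise, and similarity matrices with realistic marginal
distributions (real chemical similarities are sparse and skewed). Passing
recovery tests therefore demonstrate that the pipeline recovers planted
block structure, not that real-data accuracy is reproduced.

One property of the generator is worth stating explicitly: because the
planted interactions themselves carry block structure, the network-based
similarities computed from the training triples recover the blocks *even
when the chemical/functional matrices are flat* (within = cross). A
"no-similarity-contrast" configuration therefore still yields held-out
recovery well above chance; it nulls only the precomputed-similarity
channel, not the network channel.

## Numerical choices

* Symmetry is enforced at 1e−10 on every `SimilarityMatrix`; input files
  may be asymmetric up to 1e−6 (rounding in upstream exports) and are
  repaired by averaging with their transpose.
* Matrix I/O uses 12 significant digits, which round-trips the TSV
  writer/reader bit-identically.
* Zero-degree rows: normalization maps them to zero rows; the normalized
  Laplacian gives them an identity row (diagonal 1, off-diagonal 0).
* Ranking ties are broken lexicographically on (miRNA, EF) after the
  descending score sort, making prediction output deterministic;
  cross-validation ranks use midranks.
* The pipeline contains no randomness; seeds appear only in the synthetic
  generator.

## Problem sizes

The bundled analyses run on generated networks of 200 miRNAs × 60 EFs ×
20 diseases (≈2,400 training triples; full LOOCV refits ~2,400 folds of
two ≤200×200 solves in under a minute) and smaller 30 × 12 × 6 networks
in the unit tests. The analytic pairwise-enumeration check uses an
862-record table, the size of the curated human gold standard.

## Known limitations

* Diseases with no known interaction cannot be scored (no disease
  similarity channel).
* The integration scheme is a fixed per-pair mean; order statistics or
  rank-fusion combinations are out of scope.
* Only human-style identifiers are normalized (the `hsa-` prefix rule);
  multi-species handling is not attempted.
* The EF-space classifier is weak when most EFs share no similarity
  (sparse chemical coverage), which is why the blended default leans on
  the miRNA space in practice.
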