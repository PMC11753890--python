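# Methods

This note documents the models and procedures implemented in `targetclp`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Profile matrices and the CLBP transform

A profile matrix is any L×20 real matrix whose rows follow the sequence and
whose columns follow the canonical amino-acid order
`A R N D C Q E G H I L K M F P S T W Y V` (the PSI-BLAST header order).
Every matrix is reordered to this convention on load, which removes the most
dangerous silent failure mode of multi-matrix pipelines: column
misalignment between the evolutionary profile and the energy profile.

**Scaling.** The matrix is min-max scaled to integer intensities,
x' = round(255·(x − min)/(max − min)), rounding half to even for platform
stability. A constant matrix maps to the all-zero image. Because min-max
scaling removes gain and offset, the descriptor is exactly invariant under
x → a·x + b for a > 0; the test suite checks this property both with fixed
examples and property-based sampling.

**Code maps.** Only interior pixels act as window centers (no padding), so
an L×20 image yields (L−2)×18 centers; L ≥ 3 is required. Neighbor order is
fixed: n = 0 at the east neighbor, proceeding counter-clockwise. Three
operators per center:

- C-bit: center ≥ T, with T the mean over all pixels of the image;
- S-code: bit n set iff neighborₙ − center ≥ 0 (the sign coding is {0,1};
  a signed {−1,1} sum cannot index a histogram space);
- M-code: bit n set iff |neighborₙ − center| ≥ T_m, with T_m the mean of
  |neighbor − center| over every center/neighbor pair of the image
  (computed once per image, not per window).

All ties take the ≥ branch, so a constant image produces C = 1,
S = M = 255 everywhere — a useful analytic fixture.

**Histogramming.** For N = 8 there are 58 uniform circular codes (at most
two 0↔1 transitions); each gets its own bin in ascending code order and all
non-uniform codes share a catch-all bin (59 bins). The descriptor is the
concatenation S_u2(59) ⊕ M_u2(59) ⊕ (M_u2 × C)(118) = 236 values. This
decomposition was chosen because it is the smallest standard CLBP
decomposition whose widths sum to 236; the identifier is recorded in the
descriptor's `scheme` field so alternative decompositions remain
distinguishable. Histograms hold raw counts by default (each S/M part sums
to the number of centers — a conservation law the tests assert);
`normalize=True` divides by the center count.

**RECM-T.** Row j of the RECM-T profile is the energy row of residue j from
the 20×20 residue-wise energy contact matrix: the self-contact energy falls
on the residue's own column and pairwise energies elsewhere. The energy
table is a required runtime input read from a labelled TSV (symmetric
within 1e-9 by default, warning-only configurable); published energy values
are not bundled, and the synthetic generator provides a clearly-labelled
synthetic stand-in for tests.

**Nonstandard residues.** B, Z, X, U, O and J map to "X" by default
(strict mode rejects them, naming the record). For RECM-T the "X" row is
the column-wise mean of the 20 energy rows; for QLC grouping "X" is
excluded from counts with the effective length adjusted. This trades exact
fidelity for deterministic, documented handling of real-world inputs.

## QLC (CTD) features

Seven physicochemical properties each partition the 20 amino acids into
three groups; the shipped tables are the canonical three-group CTD tables
from the descriptor literature, stored as a package TSV and overridable per
call, since group definitions vary slightly across sources. Per property:

- Composition: percentage of residues per group (sums to 100).
- Transition: percentage of adjacent pairs whose members lie in two
  different groups, per unordered group pair; sequences shorter than 2
  effective residues yield zeros.
- Distribution: for each group, the 1-based positions of its first,
  25th-, 50th-, 75th-percentile and last occurrence, as a percentage of the
  effective length; the q-percentile occurrence of a group with n_g members
  is occurrence number max(1, ceil(q·n_g)). An absent group contributes
  five zeros.

Total: 7 × (3+3+15) = 147 features. Normalization is a per-feature z-score,
(x − x̄)/s with the sample (ddof = 1) standard deviation, with statistics
learned on the training rows only and persisted in the model bundle;
constant features are flagged and mapped to zero. A min-max [0, 1] variant
is available (`mode="minmax"`). Per-dataset (rather than per-sequence)
normalization is the only reading that is well-defined for a fixed-length
descriptor.

## Embeddings

The embedding contract is a D×L matrix of per-residue representations
pooled to a D-vector by the arithmetic mean over positions (special tokens
excluded). The deterministic mock embedder — residue-type vectors plus a
0.1-scaled sinusoidal positional encoding, all derived from one seed — is a
first-class provider used by the test suite and the default pipeline; it is
a stand-in for a pretrained model and makes no claim of biological content.
Precomputed matrices (one `.npy`/text file per sequence) are loaded
verbatim with a length check. The ESM-1b adapter needs the optional
torch/fair-esm stack and local weights; sequences beyond the model's
positional limit (1022 residues) are truncated by default and the
truncation is recorded in the embedding's provenance string.

## Differential-evolution view weighting

DE/rand/1/bin over [−2, 2]⁴, defaults N = 100, G_max = 50, CR = 0.5,
F = 0.5: per target j, three distinct other members form the mutant
v = w_r1 + F(w_r2 − w_r3); out-of-bounds mutant coordinates are clipped to
the bounds (the simplest rule that preserves the box invariant, recorded in
the result); the trial takes the mutant coordinate where rand < CR or at the
forced index k_rand; selection is strictly greedy (ties keep the target),
which makes the best-fitness trace non-decreasing by construction. All
randomness flows from one seeded generator, so runs are bit-reproducible.

The fitness of a weight vector is the mean MCC over stratified k-fold CV
(k = 5 by default) of a classifier on the weighted concatenation. The
default inner classifier is logistic regression: a full recurrent-network
fitness would cost N·G_max ≈ 5000 trainings per run, and with an L2-penalized
linear model the block scaling genuinely changes the fit, so the weights
remain meaningful. The SnBiLSTM (or any sklearn-style classifier) can be
substituted via the `classifier` parameter; the choice is persisted with the
run. Because weighting only rescales cached per-view blocks, fitness
evaluations never re-extract features.

## BTG feature selection

The tree-growth population (default 30, 100 iterations) is sorted by
fitness each iteration and split into four groups, by default 6/12/6/6
(1:2:1:1):

- best: local refinement x ← x/θ + r·x (θ = 0.8, r ~ U(0,1) per
  dimension), accepted greedily;
- competition: movement toward the two nearest (Euclidean) best-group
  trees, mixed by λ = 0.5;
- removal: the worst trees re-initialized uniformly;
- reproduction: coordinate-wise recombination of a random best tree with
  fresh random coordinates.

Continuous positions are clipped to [−4, 4] so the logistic transfer stays
responsive (at ±4 the transfer probability is already ~0.982/0.018, and the
best-group rule grows |x| geometrically, so an unbounded position space
saturates into a frozen mask). Positions are binarized per evaluation by
bit = 1 iff sigmoid(x) > rand (V-shaped |tanh| transfer available);
all-zero masks are repaired by forcing one random bit. Fitness, minimized:
α(1 − CV accuracy) + (1 − α)|mask|/D with α = 0.99, evaluated by a
5-fold-CV 1-nearest-neighbor classifier. The 1-NN evaluator precomputes
per-pair squared feature differences once, making each masked evaluation a
single matrix-vector product; it is verified against scikit-learn's
KNeighborsClassifier in the unit tests. The best mask ever seen is
returned, so the best-fitness trace is non-increasing and the recorded
fitness is exactly recomputable. These hyperparameter defaults follow
common tree-growth-algorithm practice and are all overridable; every run's
resolved configuration is persisted.

## SnBiLSTM classifier

The selected feature vector (length D) is chunked into ceil(D/width)
timesteps of `timestep_width` features (default 64), zero-padding the tail.
A bidirectional LSTM (default hidden size 128, one layer; stacking
supported) encodes the sequence; the final states of both directions are
concatenated and passed to a dense head (default one layer of 64 units)
with SELU activation, alpha dropout (rate 0.05) and LeCun-normal
initialization — the self-normalizing configuration, which keeps dense
activations near zero mean/unit variance without batch normalization — and
a sigmoid output trained with binary cross-entropy. The recurrent cells
stay standard (Glorot-initialized, forget bias 1). Training uses Adam with
decoupled weight decay (lr 1e-3, decay 1e-4, batch 32, up to 100 epochs,
early stopping after 10 epochs without a 1e-4 training-loss improvement,
seed 7). The implementation is pure NumPy with hand-derived
backpropagation through time; every analytic gradient is checked against
central finite differences in the test suite, for all five variants.

Baseline variants (`bilstm` with a ReLU head, unidirectional `lstm` and
`gru`, and a kernel-3 1-D `cnn` with global max pooling) share the
fit/predict contract and differ only in the encoder/head configuration.

The decision rule is strict: label positive iff p > Th, Th = 0.5 by
default, so a probability of exactly 0.5 is negative. Raising Th can never
increase the positive count.

Class imbalance: no resampling by default (the intended datasets are
near-balanced); `class_weight="balanced"` rescales the per-sample loss.

## Evaluation

Acc = (TP+TN)/n, Sen = TP/(TP+FN), Spe = TN/(TN+FP), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with the convention
MCC = 0 (flagged) when any denominator factor is zero. AUC uses the
rank/Mann-Whitney formulation with tie averaging; AUPR uses step-wise
average precision rather than trapezoidal interpolation, which is
optimistic on PR curves; the method is recorded in the report. Stratified
k-fold assignment (k = 5 default) is seeded and balances per-class counts
across folds to within one.

## Pipeline

Training: extract views → fit QLC normalization → learn DE weights →
weighted concatenation → BTG mask → train classifier. Prediction applies
the stored statistics, weights, mask and parameters through the same code
paths — nothing is re-fit, so no training information leaks. The model
bundle is a directory with a JSON manifest (schema-versioned config
snapshot), an `.npz` of parameter arrays, and the mask as a 0-based
newline-delimited index list; reloading a bundle reproduces predictions
bit-for-bit.

## Synthetic data: what it does and does not show

The generators emulate the *formats and statistical shape* of the real
inputs, not their biology:

- sequences: i.i.d. uniform residues — no composition bias, motifs or
  homology;
- profiles: +4 log-odds on the observed residue, −1 elsewhere, integer
  Gaussian noise (σ = 2), clamped to [−15, 15]. Under this model the
  favored column is the row argmax in roughly 70% of rows (direct
  simulation) — enough texture for the CLBP transform, but no evolutionary
  signal;
- energy matrix: symmetric, negative-dominated entries in [−8, 2], a
  plausible contact-energy range with no physical content;
- multi-view datasets: Gaussian blocks with planted mean-shifted
  informative dimensions and controllable per-view signal-to-noise.

Passing tests therefore demonstrate algorithmic correctness (exact
transforms, conservation laws, optimizer behavior, recovery of planted
signal) — not predictive performance on real clathrin data, which depends
on a real PSI-BLAST database, a published energy table and pretrained
embedding weights.

## Problem sizes used by the test and acceptance suites

The suites run at desk scale, chosen so the full run completes in a few
minutes on one CPU: CLBP oracle comparisons use 100 random profiles with
L ∈ [3, 60]; DE correctness uses the default N = 100 × 50 generations on a
quadratic; BTG recovery uses population 20 × 25 iterations on D = 20,
n = 100 (defaults are 30 × 100); classifier sanity uses hidden size 32 and
at most 40 epochs on n = 400, d = 50 (defaults 128/100). All defaults
remain as documented above; the reduced values are passed explicitly where
used.

## Known limitations

- The RECM-CLBP view is only as good as the supplied energy table; none is
  bundled.
- The ESM adapter is untested against the real model in this repository
  (no weights); the pooling and loading contracts are tested via the mock
  and precomputed paths.
- The BTG variant implements the algorithmic contract with
  literature-standard defaults; other binarization or grouping choices are
  possible and selectable but not exhaustively compared.
- NumPy training is single-threaded and desk-scale; very wide inputs
  (tens of thousands of features) would need minibatched BLAS-heavy
  configurations or a framework port.
- The DE fitness default (linear classifier) is a deliberate proxy; see
  the integration section.
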