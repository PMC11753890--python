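# targetclp

Clathrin proteins are the adaptor proteins of the vesicle coat and central to
clathrin-mediated endocytosis; recognizing them from sequence alone is a
binary protein-classification problem (clathrin vs. non-clathrin, with
vesicular-transport proteins as hard negatives). `targetclp` implements a
complete multi-view prediction pipeline for this task, aimed at
bioinformaticians who have sequences, PSI-BLAST profiles and (optionally)
protein-language-model embeddings, and want a reproducible, fully tested
implementation of every stage.

## The method

Each protein of length *L* is represented by four feature views:

1. **PSSM-CLBP (236)** — the *L*×20 PSI-BLAST position-specific scoring
   matrix *P* is min-max scaled to an 8-bit image *P_I* and described by
   completed local binary patterns over 3×3 windows (*R* = 1, *N* = 8).
   Per interior pixel three operators are computed: the center bit
   *C* = 1[*P_I*(c) ≥ *T*] with *T* the global image mean; the sign code
   *S* = Σₙ sₙ2ⁿ with sₙ = 1[neighborₙ − center ≥ 0]; and the magnitude code
   *M* = Σₙ mₙ2ⁿ with mₙ = 1[|neighborₙ − center| ≥ *T_m*], *T_m* the
   image-wide mean absolute difference. Uniform-pattern (u2) histograms —
   59 bins for *S*, 59 for *M*, and a joint 118-bin *M*×*C* histogram —
   concatenate into the 236-dim descriptor.
2. **RECM-CLBP (236)** — the same transform applied to the RECM-T profile,
   whose row *j* is the 20-vector of predicted contact energies of residue
   *j* against all standard amino acids, looked up in a 20×20 symmetric
   residue-wise energy contact matrix (a runtime input; a synthetic
   stand-in ships for tests).
3. **QLC (147)** — composition/transition/distribution (CTD) indices over
   three-group partitions of seven physicochemical properties
   (hydrophobicity, normalized van der Waals volume, polarity,
   polarizability, charge, secondary structure, solvent accessibility):
   per property 3 C + 3 T + 15 D features, z-scored with statistics learned
   on the training set.
4. **ESM (1280)** — per-residue embeddings from a protein language model
   (ESM-1b, last hidden layer, 1280×*L*), mean-pooled over positions.
   A deterministic mock embedder and a precomputed-file loader make the
   pipeline testable and runnable without pretrained weights.

The views are fused by **weighted concatenation** *w*₁·ESM ⊕ *w*₂·PSSM-CLBP ⊕
*w*₃·QLC ⊕ *w*₄·RECM-CLBP (total width 1899), with **w** ∈ [−2, 2]⁴ learned
by classic DE/rand/1/bin differential evolution (mutation
*v* = *w*_r1 + *F*(*w*_r2 − *w*_r3), binomial crossover, strict greedy
selection; defaults *N* = 100, *G*max = 50, *CR* = 0.5, *F* = 0.5)
maximizing mean stratified *k*-fold CV MCC. A **binary tree-growth (BTG)**
metaheuristic then selects a feature subset, minimizing
α·(1 − CV accuracy) + (1 − α)·|subset|/D. The final classifier is the
**SnBiLSTM**: the selected vector is chunked into timesteps, encoded by a
bidirectional LSTM, and classified by a SELU/alpha-dropout
(self-normalizing) dense head with a sigmoid output; a protein is called
clathrin iff its predicted probability strictly exceeds *Th* = 0.5.
Evaluation reports Acc, Sen, Spe, MCC, AUC and AUPR under stratified
*k*-fold cross-validation.

Everything — including the recurrent network and its backpropagation — is
implemented in NumPy/SciPy/scikit-learn; no deep-learning framework is
required. Estimator classes (`DEWeightIntegrator`, `BTGSelector`,
`SnBiLSTMClassifier`, `QLCNormalizer`) follow scikit-learn's fit/transform
conventions and compose with its model-selection tools.

## Worked example

```python
import numpy as np
from targetclp import pssm_clbp, recm_clbp, qlc_vector
from targetclp.synthetic_data import (
    SynthSpec, gen_sequences, gen_profile, gen_energy_matrix,
)

rec = gen_sequences(SynthSpec(n_sequences=1, length_range=(60, 60), seed=7))[0]
desc = pssm_clbp(gen_profile(rec, seed=7))
print("PSSM-CLBP length:", len(desc.vector))          # 236
print("scheme:", desc.scheme)                          # S_u2(59)+M_u2(59)+M_u2xC(118)
print("S-histogram mass:", int(desc.vector[:59].sum()))  # 1044 = (60-2)*18
q = qlc_vector(rec)
print("QLC length:", len(q))                           # 147
print("hydrophobicity C:", np.round(q[:3], 2))         # [26.67 35.   38.33], sums to 100
print("RECM-CLBP length:",
      len(recm_clbp(rec, gen_energy_matrix(seed=3)).vector))  # 236
```

The histogram-mass line shows the CLBP conservation law: each of the S and M
histograms holds exactly one count per interior image pixel, (L−2)·18 of
them. The composition triple is the percentage of residues in each
hydrophobicity group, so it sums to 100.

The same stages are available from the shell. On a 20-protein synthetic set
(`embed-dim 64`, so the table is 20×683):

```console
$ targetclp synth --out-dir demo --n 20 --min-len 40 --max-len 80 --seed 11
wrote 20 synthetic records to demo
$ targetclp extract --fasta demo/sequences.fasta --pssm-dir demo/pssm \
    --recm demo/recm.tsv --labels demo/labels.tsv --embed-dim 64 \
    --out demo/features.tsv
wrote 20 x 683 feature table to demo/features.tsv
$ targetclp integrate-de --table demo/features.tsv --n-pop 10 --max-gen 5 \
    --k 2 --seed 1 --out demo/weights.json
weights: [0.4870104411489615, -2.0, 0.5249423904532347, 0.21693880498195917]
$ targetclp select-btg --table demo/features.tsv --weights demo/weights.json \
    --population 10 --iterations 10 --k 2 --seed 1 --out demo/mask.txt
selected 335/683 features (final fitness 0.3514)
```

The four weights are the learned view coefficients (ESM, PSSM-CLBP, QLC,
RECM-CLBP) inside the [−2, 2] bounds; the reported fitness is the minimized
BTG objective (labels here are random, so it stays far from 0).
`targetclp train` / `targetclp predict` run the full pipeline around a
persisted model bundle, and `targetclp cv` cross-validates the classifier on
a feature table.

## Layout

- `targetclp.io_formats` — FASTA, PSI-BLAST ASCII PSSM, energy-matrix TSV,
  feature-table TSV, model-bundle persistence
- `targetclp.clbp_transform` — profile-matrix scaling, CLBP code maps,
  u2 histograms, RECM-T construction
- `targetclp.qlc_features` — CTD grouping tables, C/T/D indices, learned
  normalization
- `targetclp.embeddings` — mean pooling, deterministic mock embedder,
  precomputed loader, optional ESM adapter
- `targetclp.de_integration` — weighted concatenation, differential
  evolution, CV-MCC fitness
- `targetclp.btg_selection` — binary tree-growth search, masked 1-NN
  evaluator, mask bookkeeping
- `targetclp.snbilstm_classifier` — NumPy BiLSTM/GRU/CNN encoders with
  BPTT, SELU dense head, Adam training
- `targetclp.evaluation` — Acc/Sen/Spe/MCC/AUC/AUPR, stratified k-fold
- `targetclp.synthetic_data` — seeded generators for every pipeline input
- `targetclp.pipeline`, `targetclp.cli` — orchestration and the
  `targetclp` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
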