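# dbpstack

A toolkit for sequence-based prediction of DNA-binding proteins (DNA-BPs):
multi-family protein feature encoding, staged recursive feature elimination,
a correlation-guided two-layer stacking ensemble, benchmark curation with
sequence-identity thresholds, and a full evaluation/statistics protocol.
Everything runs offline on seeded synthetic fixtures, so the whole pipeline
is testable without downloads, homology searches or structure predictors.

## Who it is for

Computational biologists building or benchmarking binary protein-function
classifiers from primary sequence, evolutionary profiles (PSSMs produced by
iterative homology search) and per-residue structural predictions
(secondary-structure probabilities, accessible surface area, backbone
torsion angles, half-sphere exposure).

## The model

A protein `P = R1 R2 ... RL` is mapped to a fixed-length descriptor vector
`[ψ1 ... ψΩ]` (the pseudo-amino-acid-composition tradition): compositions
(AAC/DPC/TPC and grouped/gapped variants), order-aware families (CTD,
conjoint triads, quasi-sequence-order, PAAC/APAAC, Moran/Geary/Moreau-Broto
autocorrelation), PSSM descriptors over the logistic-normalized L×20
log-odds matrix (local pseudo-PSSM, bigrams, composition, auto-covariance,
segmented distribution), and structure-profile statistics.

Feature selection is recursive elimination with internal stratified K-fold
cross-validation, run coarse-to-fine: large elimination steps first, each
subsequent stage restarting from the previous best size plus one step of
margin, down to single-feature elimination.

The classifier is a stacking ensemble:

* base layer — a soft-voting ensemble of a decision tree, AdaBoost and
  linear discriminant analysis (the three least Pearson-correlated of the
  candidate classifiers) alongside an RBF-kernel SVC with grid-searched
  `C = 5.445`, `γ = 0.00237`, Platt-calibrated;
* meta layer — logistic regression trained on held-out base probabilities
  generated by inner stratified cross-validation (leakage-free).

Evaluation reports ACC, SN, SP, PREC, F1, MCC, AUROC and AUPR, with
stratified K-fold and jackknife (leave-one-out) schemes, class-stratified
bootstrap replicates, low-prevalence subsampling, and Friedman + Holm
multi-classifier comparison.

Dataset curation drops fragments (length ≤ 50) and sequences with unknown
residues, then enforces a pairwise sequence-identity ceiling (default 25%,
global alignment, identity over the shorter length) within and between
classes by greedy incremental clustering with longest-representative
retention, before a per-class stratified 80-20 split.

## Worked example

```bash
dbpstack fixtures --n-pos 80 --n-neg 80 --seed 1 --signal-strength 1.0 --out-dir run/train
dbpstack fixtures --n-pos 80 --n-neg 80 --seed 2 --signal-strength 1.0 --out-dir run/test
dbpstack extract  --fasta run/train/benchmark.fasta --encoders AAC,GAAC --out-dir run/train
dbpstack extract  --fasta run/test/benchmark.fasta  --encoders AAC,GAAC --out-dir run/test
dbpstack train    --features run/train/features.tsv --labels run/train/labels.tsv --out-dir run/model
dbpstack evaluate --features run/train/features.tsv --labels run/train/labels.tsv \
                  --scheme kfold:5 --out-dir run/eval
dbpstack predict  --model run/model/model.joblib --features run/test/features.tsv --out-dir run/pred
```

`run/eval/metrics.tsv` from this exact invocation:

```
ACC	1.000000
SN	1.000000
SP	1.000000
PREC	1.000000
F1	1.000000
MCC	1.000000
AUROC	1.000000
AUPR	1.000000
```

At `--signal-strength 1.0` the positive class draws its residues from a
disjoint composition (mass on K/R/H/S/T, mimicking the basic/polar bias of
nucleic-acid contacts), so a perfect cross-validated score is the expected
outcome — it confirms the encoders carry the class signal and the ensemble
recovers it. Lower signal strengths give intermediate, noisier scores.
`run/pred/predictions.tsv` lists one row per test protein with the
positive-class probability and the 0.5-threshold label.

The same pipeline is available as library calls (`gen_benchmark`,
`encode_records`, `fit_stack`, `cross_validate`, ...); see `docs/methods.md`
for the scientific details and design choices.

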