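# Methods

This note documents the models, defaults and design choices behind
`dbpstack`, and what the synthetic-fixture tests do and do not demonstrate
about real data.

## Problem setting

Binary classification of proteins into DNA-binding (positive) and
non-binding (negative) from three information sources: the primary sequence
alone; an L×20 position-specific scoring matrix (PSSM) of integer log-odds
from iterative homology search; and per-residue structural predictions
(3-state secondary-structure probabilities, accessible surface area,
backbone torsion angles φ/ψ/θ/τ, half-sphere exposure up/down counts).
The toolkit only *consumes* PSSMs and structural profiles — producing them
requires homology search and a structure predictor, which are out of scope.

## Sequence representation and encoders

Every encoder maps a variable-length sequence to a fixed-length vector
whose components preserve composition and, for the order-aware families,
local sequence-order information. The registry (26 families, ~16k default
dimensions) and the defaults that matter:

* **Compositions** — AAC (20), DPC (400), TPC (8000), grouped variants
  GAAC/GDPC/GTPC over five physicochemical classes (aliphatic, aromatic,
  positive, negative, uncharged polar), gapped dipeptides and grouped pairs
  with gaps 1–5 (a gap of *g* means *g* residues between the pair). All are
  frequency-normalized: each family sums to 1.
* **DDE** — dipeptide deviation from the expectation under standard-code
  codon counts: `(Dc − Tm) / sqrt(Tm (1 − Tm) / (L − 1))` with
  `Tm = (Ca/61)(Cb/61)`.
* **CTD** — composition and transition descriptors over 13 three-group
  attribute partitions (39 features each). Seven partitions are the
  canonical published groupings (hydrophobicity, normalized van der Waals
  volume, polarity, polarizability, charge, secondary-structure propensity,
  solvent accessibility). The remaining six hydrophobicity-variant
  partitions are constructed as tertile splits of packaged
  hydrophobicity-related scales; the exact historical groupings differ in
  detail, and any user-supplied partition table can be passed instead. The
  `Dubchak` encoder is the full C/T/D triple (21 values) over the seven
  canonical partitions (147).
* **Conjoint triads** — 7-class alphabet, 343 triad frequencies; the
  k-spaced variant inserts k ∈ {0..3} residues between triad members.
* **Sequence-order coupling** (SOCNumber/QSOrder, λ = 8, weight 0.1) —
  parameterized by residue-pair distance matrices. The packaged defaults
  are two distance matrices computed from the shipped property scales
  (hydropathy/hydrophilicity/mass and volume/pI/charge/aromaticity,
  Euclidean over standardized scales, normalized to [0, 1]); the
  literature matrices can be supplied by the caller.
* **PAAC / APAAC** (λ = 8, w = 0.05) — Chou-style pseudo-compositions with
  the classic hydrophobicity/hydrophilicity/side-chain-mass scales,
  standardized over the 20 residues.
* **Autocorrelation** (Moran, Geary, normalized Moreau-Broto; max lag 8) —
  eight packaged scales (Kyte–Doolittle hydropathy, Hopp–Woods
  hydrophilicity, consensus hydrophobicity, side-chain mass, volume,
  isoelectric point, net charge, aromaticity), standardized before use.
  A zero-variance value sequence (homopolymer) yields 0 by convention.
* **Positional families** — PSN is the mono+digram composition of the
  N- and C-terminal 5-residue windows; MPS/BPS are per-quartile-segment
  monogram/bigram compositions; NNB is, for each ordered residue pair
  (a, b), the mean inverse distance from occurrences of a to the nearest b.
  The cited prior definitions of these four are ambiguous; these are
  documented interpretations with the intended dimensions.
* **KNNpeptide** — the positive fraction among the top-k most
  alignment-similar training sequences, for k fractions
  {2, 5, 10, 20, 30}%. Because it depends on labels, it is excluded from
  the default batch bank and must be computed fold-internally during
  cross-validation to avoid label leakage.

Every division with a zero denominator yields 0, never NaN.

## PSSM descriptors

Raw log-odds are logistic-normalized `N = 1/(1+exp(−S))` after clamping to
[−30, 30] (real log-odds rarely leave [−16, 16]; the clamp keeps the output
strictly inside (0, 1) in float64). Column order is remapped from the
PSI-BLAST file order to alphabetical once, at parse time, so all encoders
are invariant to trailing non-score file columns.

* **Local pseudo-PSSM** — per contiguous segment (equal splits, remainder
  to the last segment): 20 column means plus 20·λ averaged squared
  lag-differences; defaults n ∈ {1..5} concatenated, λ = 8 (n = 1 is the
  global form).
* **Bigram / one-lead bigram** — mean lagged outer products of rows
  (lag 1 or 2), 400 each.
* **Composition** — rows grouped by query residue, group-wise column
  means; absent groups contribute zeros (400).
* **Auto-covariance** — per-column lagged covariances, lags 1..8 (160).
* **Segmented distribution** — per column, the fractional positions at
  which the running column sum reaches k/n of the column total
  (default n = 4; a zero-total column reports 0).

## Structure descriptors

Torsion angles enter all statistics as (sin, cos) pairs, removing the
−180°/180° discontinuity (8 columns). ASA is used raw by default (the
upstream predictor's normalization convention is not assumed); a
max-normalization flag exists. Statistics per channel: column means
(composition), mean lag-1 outer products (bigram), per-column lagged
covariances (auto-covariance, lags 1..8). Secondary-structure occurrence
and composition use the per-residue argmax state. Output dimension depends
only on (channel, statistic, lag), never on length.

## Staged feature selection

Each stage performs recursive elimination on the current feature set:
fit a seeded 100-tree random forest, record the stratified K-fold CV
accuracy of the current set, drop the `step` lowest-importance features
(impurity importance; ties broken by column order), repeat. The subset
size maximizing mean CV accuracy wins; ties prefer the smaller size
(parsimony, deterministic). The forest is refit at every elimination
(standard recursive-elimination semantics).

Stages run coarse-to-fine with strictly decreasing steps. Stage s+1
receives the top `best_k_s + step_s` features of stage s — the carryover
margin equals the previous step, mirroring the benchmark-scale schedule
1000 → 100 → 25 → 1 in which a best size of 6856 under step 1000 hands
7856 features to the next round, 1856 + 100 → 1956, and 606 + 25 → 631.
The full-scale default schedule uses 10-fold CV; the desk-scale tests and
the acceptance script use 3–5 folds and 20–50 trees to keep runtimes in
minutes — a problem-size choice, with the selection semantics unchanged.

## Stacking ensemble

Base layer: a soft-voting ensemble of decision tree + AdaBoost + linear
discriminant analysis, and an RBF SVC with C = 5.445, γ = 0.00237
(grid-searched defaults), sigmoid(Platt)-calibrated. These three voting
members are the least mutually Pearson-correlated of the candidate
classifiers' held-out probability vectors; the `correlation_matrix`
diagnostic reproduces that selection on any probability table (zero
variance vectors are reported as undefined and excluded).

Meta layer: logistic regression on the two base positive-class
probabilities. Meta-features are generated by 5-fold inner stratified CV —
for every training sample, only base models that did not see it contribute
its meta-feature (a unit test re-derives the fold-wise predictions and
checks equality). A naive refit-on-full-train variant is expressible via
`meta_input`/fold settings but the leakage-free variant is the default and
the one tested. Features are z-scored inside the model with training-set
statistics only (the RBF kernel is scale-sensitive). Decision threshold
0.5. Fixed seeds make fitted predictions bit-identical.

Bias/variance: bootstrap MSE decomposition over a held-out stratified 30%
split — per test point, mean squared error across refits equals
(mean prediction − y)² + prediction variance exactly, so the two reported
numbers sum to the average MSE.

## Evaluation and statistics

Threshold metrics are exact ratios of confusion counts; zero-denominator
metrics report 0 with a flag. AUROC is the trapezoidal ROC area (equal to
the tie-aware normalized Mann–Whitney U, asserted against exhaustive
pairwise concordance in tests); AUPR is the non-interpolated
precision-recall area. Cross-validation pools held-out probabilities over
folds before computing metrics (micro-averaging), which makes the
jackknife — one prediction per fold — well-defined and makes k = n
identical to leave-one-out. Bootstrap replicates resample each class with
replacement to its original size (proportions preserved exactly);
replicate r uses seed `seed + r`. Low-prevalence subsampling keeps all
negatives and the positive count whose prevalence is closest to the
target (178 negatives at target 6.3% keep 12 positives).

The Friedman test ranks methods per dataset (rank 1 best, ties averaged)
and uses the tie-corrected chi-squared statistic with k − 1 degrees of
freedom; the decision compares against the chi-squared critical value at
α (11.07 at df = 5, α = 0.05). Post-hoc pairwise comparisons use the
rank-difference z statistic with SE = sqrt(k(k+1)/(6N)) and Holm
step-down adjustment.

## Dataset curation

Filters: drop length ≤ 50 (possible fragments) and any sequence containing
a non-canonical residue (X, and likewise B/Z/U/O/J — the encoders assume a
strict 20-letter alphabet). Identity oracle: global pairwise alignment
(match +5, mismatch −4, gap open −10, extend −0.5), identity = identical
aligned columns / shorter length — the greedy-clustering tool convention.
Unrelated random sequences score ~0.1 under these penalties, well below
the 25% default threshold; near-duplicates score > 0.9.

Clustering is greedy-incremental in decreasing-length order (ties by id):
a sequence joins the *first* cluster whose representative it matches at or
above threshold, else founds a cluster; the longest member (ties:
lexicographically smallest id) represents each cluster. Under this order
the founder is always the representative, so a single pass already leaves
representatives pairwise below threshold; the reduction nevertheless
iterates and then *verifies exhaustively* (all pairs, capped at 2000
sequences), erroring with the offending pairs if violations ever remain —
a guard that matters if a caller supplies a different oracle or ordering.
Between-class reduction keeps every positive and discards any negative
matching any positive at ≥ threshold. The 80-20 split shuffles each class
with a seeded generator; test size is round(0.2·n) per class (890 + 890
inputs yield 712/178 per class, 1780 total).

## Synthetic fixtures: what they emulate and what they do not

`gen_benchmark` draws i.i.d. residues; positives mix a uniform background
with a class-specific composition concentrated on K/R/H/S/T (the
basic/polar enrichment of nucleic-acid-binding interfaces) with mixing
weight `signal_strength` ∈ [0, 1]; negatives are pure background. Lengths
are uniform on [51, 120] by default so the fragment filter is not
triggered accidentally. An optional dipeptide-bias map adds first-order
excess probabilities. `gen_pssm` elevates row i at residue R_i's column by
`round(strength · 8)` over integer noise uniform on [−3, 3] (the magnitude
range of real log-odds); `gen_struct_profile` draws Dirichlet SS rows,
folded-normal ASA, uniform torsions and Poisson HSE counts. All generators
are pure functions of (inputs, seed).

These fixtures establish that the pipeline is *correct* (encoders compute
their formulas, selection recovers planted signal, the ensemble learns a
separable composition difference, curation enforces its threshold,
everything is reproducible). They do **not** establish real-world
predictive performance: real proteins have domain structure, phylogenetic
correlation and far subtler class signals than a composition shift, and
real PSSMs/structure profiles encode conservation patterns the noise
models here do not. Published benchmark-scale figures additionally require
the real curated sequence sets plus homology-search PSSMs and predicted
structure profiles, none of which are reproducible offline.

## Numerical conventions and limitations

* Zero denominators yield 0 (flagged where it matters), never NaN.
* Tie-breaks are deterministic everywhere (smaller subset size, smaller C
  then γ, lexicographic ids, stable sorts).
* The full 26-family bank at defaults is ~16k dimensions; the published
  55856-dimension inventory is not reproducible because the per-family
  parameterization behind it was never itemized, and no attempt is made
  to match it.
* Sequences lacking a PSSM raise a descriptive error; callers fall back
  to sequence-only features explicitly rather than silently.
* Exhaustive identity verification is O(n²) alignments and capped at 2000
  sequences; beyond that, trust-but-don't-verify is not offered.
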