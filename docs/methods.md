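# Methods

## Problem and model

`amyloidkit` classifies whole protein sequences as amyloid-forming
(positive) or not (negative) from primary sequence alone. The pipeline has
three stages: sequence encoding, feature selection, and a single-hidden-layer
multilayer perceptron (MLP).

### Encoders

**SVMProt-188D.** A sequence of length *L* is encoded as 188 numbers: the
20 amino-acid frequencies N_i/L, followed, for each of 8 physicochemical
properties that partition the 20 residues into three classes (hydrophobicity,
normalized Van der Waals volume, polarity, polarizability, charge, surface
tension, secondary-structure propensity, solvent accessibility), by the CTD
descriptors:

* **C** (composition, 3 values): per-class residue frequency;
* **T** (transition, 3 values): for each unordered class pair (r, s), the
  number of adjacent residue pairs with one member in class r and the other
  in class s, in either order, divided by L − 1;
* **D** (distribution, 15 values): for each class occurring n ≥ 1 times at
  1-based positions p_1 < … < p_n, the chain-length percentages
  100·p_m/L at m = 1, ⌈0.25n⌉, ⌈0.50n⌉, ⌈0.75n⌉, n. An empty class
  contributes five zeros.

The transition convention (symmetric pairs over L − 1) and the distribution
anchor rule (ceiling on 1-based positions, with the first and last
occurrence as exact anchors) are the standard CTD conventions; they produce
exactly 20 + 21 × 8 = 188 features. One printed variant of the
solvent-accessibility grouping circulating in the literature lists M in two
classes and omits W; we use the standard disjoint partition
(ALFCGIVW / RKQEND / MPSTHY) so that each property is a true partition of
the alphabet, which downstream normalization identities assume.

**TPC.** The 20³ = 8000 overlapping tripeptide frequencies N_i/(L − 2),
indexed lexicographically (AAA … YYY). Requires L ≥ 3.

Non-standard residue codes (B, Z, X, U, O), gaps and whitespace are removed
during sanitization rather than remapped; *L* counts the sequence after
removal. This keeps every frequency formula well defined without inventing
substitution rules.

### Feature selection

**MRMD** ranks the 188 CTD features by score MR_i + MD_i, where
MR_i = |Pearson correlation of feature i with the labels| and MD_i is the
mean distance from feature column i to every other feature column
(Euclidean by default; 1 − cosine similarity and 1 − Tanimoto coefficient
are alternatives, and MEAN averages the three). MR and MD are each min–max
normalized across features before summing: |PCC| is bounded in [0, 1] while
distances are unbounded and scale with the feature's units (the ×100
distribution block would otherwise dominate the score outright). Distances
are computed between feature columns over samples, averaging over all other
features; similarities are converted to distances so that redundancy is
penalized, with zero-norm columns contributing zero distance. Ties in every
ranking break by ascending feature index (stable sort) for reproducibility.
The default subset size is 121.

**Binomial-distribution (BD) ranking** scores each tripeptide by how
non-random its class-specific occurrence count is. With N_i total
occurrences of tripeptide i, n_ij of them in class j, and
q_j = (total tripeptide occurrences in class j)/(total occurrences),
P_ij = Σ_{k=n_ij}^{N_i} C(N_i, k) q_j^k (1 − q_j)^{N_i−k} is the upper
binomial tail and CL_ij = 1 − P_ij the confidence level; each tripeptide
takes the larger of its two class CLs. q_j counts occurrences, not
per-sample presence — the most literal reading of a class's "share of all
tripeptides". Tails are evaluated with the binomial survival function;
because 1 − P rounds to exactly 1.0 in double precision once P < ~1e−16,
the rank order is computed on P directly (identical ordering, no precision
collapse). Tripeptides absent from every sample get CL 0 and rank last.
Default subset size 425; the multi-feature input to the classifier is the
121 selected CTD features concatenated with the 425 selected tripeptide
frequencies (546 columns).

**Incremental ranked-subset evaluation** scores the nested subsets
D_1 ⊂ D_2 ⊂ … (top-k features in rank order) by stratified k-fold
cross-validation accuracy of a support-vector classifier (scikit-learn
`SVC` defaults; the evaluator is pluggable) under a seed-fixed fold split
shared across all k. The curve reports the argmax k and the smallest k
within a configurable tolerance of the maximum — the parsimony rule for
choosing a small subset whose accuracy is near the peak.

### Classifier

One hidden layer of ⌊(d + 2)/2⌋ logistic units for d input features, a
2-class output, constant learning rate 0.3, 500 full-batch gradient-descent
epochs, momentum 0 and no weight decay. The implementation wraps
scikit-learn's `MLPClassifier`, whose binary model uses a single logistic
output unit — mathematically equivalent to a 2-unit softmax output for two
classes. Inputs are standardized per feature with statistics from the
training data only; at learning rate 0.3 the raw tripeptide-frequency
scale (≈1/L) makes unstandardized training impractically slow or unstable.
Training is deterministic given data and seed, and fitted models
round-trip through `save_model`/`load_model` with identical predictions.
No class re-weighting is applied despite the 165:382 design imbalance; the
expected qualitative consequence (specificity above sensitivity) is visible
in evaluation output.

### Evaluation

ACC = (TP+TN)/(TP+TN+FP+FN) (reported as a percentage), SE = TP/(TP+FN),
SP = TN/(TN+FP), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))
with MCC = 0 whenever a denominator factor is 0. Cross-validation is
stratified with a fixed, logged seed; metrics are computed on the confusion
counts pooled over folds (one ACC/SE/SP/MCC per experiment), with per-fold
metrics as a secondary output. ROC curves sweep all descending unique score
thresholds with ties grouped, start at (0,0), end at (1,1), and AUC is the
trapezoid integral, which equals the Mann–Whitney concordance probability.

## Synthetic data

The generator emulates the shape of a curated amyloid benchmark without
claiming biophysical realism: 165 positive and 382 negative sequences by
default, lengths uniform on [50, 500], residues drawn i.i.d. from a uniform
background over the 20 letters. Two kinds of class signal can be planted:

* **Tripeptide enrichment** — for each planted (tripeptide, probability p,
  class) triple, every sequence of that class receives one insertion
  attempt: with probability p a random window of 3 consecutive positions is
  overwritten by the tripeptide. Overwriting (rather than inserting)
  keeps the length distribution independent of enrichment. The default
  planted set is five Q/N-rich and aromatic/aliphatic triples (NNQ, QYQ,
  VFF, IYI, SSW) at p = 0.8.
* **Hydrophobicity composition bias** — the positive class's background
  adds 0.15 probability mass to the polar/charged hydrophobicity class-1
  letters (RKEDQN), redistributed proportionally. 0.15 is a moderate,
  clearly detectable compositional shift at the default sample sizes.

What the generator does **not** emulate: residue autocorrelation, realistic
length/composition distributions, homology structure between sequences, or
the actual sequence determinants of aggregation. Passing recovery tests
therefore demonstrate that the pipeline detects the kinds of signal it is
designed for at realistic sample sizes — not that it attains any particular
accuracy on real proteins.

### Parameter recovery and the null

The recovery suite generates a reduced dataset of 200 sequences (60
positive / 140 negative, preserving the 165:382 imbalance), encodes both
blocks, and checks three things: (a) all five planted tripeptides fall in
the BD ranking's top 20; (b) the three hydrophobicity-composition features
rank above the median MRMD rank; (c) pooled 10-fold CV accuracy of the MLP
on the selected 546-dim multi-feature reaches at least 0.85. The reduced
problem size and a 50-epoch training budget keep a full suite run to a few
seconds while leaving the planted signals comfortably detectable.

The cross-validated accuracy in (c) nests feature selection inside each
training fold (`AmyloidPipeline`): both rankers are re-fitted on the
training portion only. Ranking once on the full dataset and
cross-validating afterwards leaks label information through the selected
columns — with 8000 candidate tripeptides and 200 samples, that selection
bias alone yields near-perfect "accuracy" on label-free data. With nested
selection the signal-free null (zero enrichment, zero bias) sits near the
majority-class rate of 0.70; an overfit classifier on pure noise tends to
land slightly below the majority rate, since any deviation from
always-majority prediction is uninformative.

## Numerical and design choices

* Binomial tails via the survival function (log-space internally), exact to
  1e−12 against rational arithmetic for N ≤ 20.
* Min–max normalization maps a constant score block to zeros; a matrix
  whose features are all constant is an error (no ranking possible).
* MCC, SE and SP use the zero-denominator → 0 (or empty-class) conventions
  above; degenerate all-one-class predictions are representable.
* The feature-matrix TSV uses 10-significant-digit formatting, making a
  write/read/write cycle byte-stable.
* Seeds: every stochastic stage (generation, fold assignment, weight
  initialization) takes an explicit integer seed and is reproducible
  bit-for-bit from it.

## Known limitations

* Headline accuracies on real amyloid benchmarks depend on the original
  training toolkit's optimizer internals (batch schedule, momentum,
  normalization), which are underdetermined; plain full-batch gradient
  descent is the simplest faithful reading and may differ by a few points.
* The MRMD distance term is scale-sensitive by construction: high-magnitude
  blocks (the ×100 distribution features) receive systematically larger MD
  scores. Min–max normalization bounds the effect but does not remove it;
  this mirrors the method as published rather than correcting it.
* BD ranking assumes independent tripeptide draws; overlapping occurrences
  and length variation violate independence mildly. The ranking is used
  ordinally, so this affects CL calibration, not selection order.
* The evaluator SVM's hyperparameters in the subset-curve loop are
  scikit-learn defaults; subset-size choices can shift under other kernels.
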