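# Methods

This package implements a classification structure–property relationship
(CSPR) workflow for P-glycoprotein (Pgp) screening: two separate binary
tasks (inhibitor vs. non-inhibitor, substrate vs. non-substrate) are
modelled from a small panel of interpretable molecular descriptors. The
note below records the models, the parameters that matter, the synthetic
data the tests run on, and the numerical choices made where the design was
genuinely open.

## Pipeline

1. **Curation.** Input compound lists (SMILES + class label) are
   canonicalized with RDKit; removal proceeds in a fixed order —
   unparseable structures, compounds above the molecular-weight limit
   (default 1000 Da, average atomic masses with implicit hydrogens),
   exact duplicates (same canonical SMILES and label, first occurrence
   kept), and *overlapping* compounds (one canonical SMILES under two
   distinct labels, including cross-task, removed from every class).
   Each removal is logged with its reason; the census reports raw
   per-label counts so upstream bookkeeping discrepancies stay visible.
   Multi-fragment (salt) SMILES are kept verbatim and flagged; no
   tautomer or charge standardization is attempted.

2. **Descriptors.** Seven 2-D descriptors per compound: MW; rotatable
   bonds (RBN: single acyclic bonds between two non-terminal heavy atoms,
   amide C–N excluded — implemented directly because common library
   variants also exclude esters); ring count (nCIC: cyclomatic number of
   the heavy-atom graph); H-bond donors (nHDon: H on N or O); H-bond
   acceptors (nHAcc: N + O + F atom count — an atom-count convention, so
   integer decision-tree cutoffs such as "nHAcc ≤ 4" stay meaningful);
   Ghose–Crippen/Wildman ALogP; and Ertl TPSA (both via RDKit, and
   cross-checked in the tests against OpenBabel's independent
   implementation). Descriptors are computed from the re-parsed canonical
   SMILES so equivalent input strings give bit-identical values. Six
   quantum chemical descriptors (mean absolute charge Q_m, total energy,
   dipole, HOMO, LUMO, gap) are *ingest-only*: merged from an external
   CSV by id and validated (gap = LUMO − HOMO within 1e-3 eV); no
   electronic-structure calculation is performed. An optional Gasteiger
   surrogate for Q_m exists for synthetic exercises and is always flagged
   `surrogate=true`.

3. **Feature selection.** Pearson intercorrelation matrix over the
   descriptor table (constant columns: correlation defined as 0 with a
   warning), then a greedy left-to-right scan removing any later column
   with |r| ≥ the cutoff (default 0.7) against a surviving column. The
   cutoff applies to |r| — anti-correlated descriptors are equally
   redundant. The kept set is a fixed point of the procedure and is
   invariant to row order.

4. **Imbalance correction.** The majority (positive) class is split by
   fuzzy C-means into k = max(2, ceil(n_pos/n_neg)) clusters on z-scored
   features. Each cluster, joined with the full negative class, is scored
   by stratified 10-fold cross-validated decision-tree performance
   (clusters smaller than 10 fall back to leave-one-out, logged); the
   cluster with the highest MCC — ties broken by accuracy, then cluster
   size, then lower cluster id — becomes the representative positive set.
   This is undersampling by cluster selection; no synthetic rows are
   created. Cross-validated (rather than training-set) scoring was an
   open choice, made to discourage selecting clusters that merely overfit.

5. **Models.** The decision tree is a bespoke gain-ratio inducer
   (C4.5-family): binary numeric splits, candidate thresholds at
   midpoints between adjacent distinct sorted values where the class
   composition changes, "≤ goes left", growth until purity or a minimum
   child size (default 2), pessimistic-error pruning at confidence 0.25.
   Zero-gain candidates remain eligible while a node is impure: stopping
   on zero gain would make XOR-like interactions unlearnable, and the
   pruning pass removes the unsupported structure this permits on noise.
   Ties between splits go to the lower column index, then the lower
   threshold, making induction deterministic. Each leaf yields one
   conjunctive if-then rule; the rule list is mutually exclusive and
   exhaustive and round-trips through its text rendering. MLP and SVM
   learners delegate to scikit-learn behind the same train/predict
   contract, with hyperparameters chosen from a configurable grid by
   stratified 10-fold CV MCC (defaults: one hidden layer sized
   (features+classes)/2 or features, learning rates 0.3/0.1, 500 epochs;
   RBF/linear kernels, C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1}).

6. **Validation.** Accuracy, sensitivity and specificity as percentages
   and MCC from the pooled confusion matrix; any zero factor in the MCC
   denominator defines MCC = 0, and an undefined sensitivity/specificity
   is reported as missing with a warning. Cross-validation pools
   predictions over folds into a single confusion matrix (well-defined
   for small folds, unlike averaging per-fold metrics). The external
   split holds out 15 % per class, with |train| = floor(0.85·n + 0.5);
   "PCA-guided random sampling" is realized as: per class, z-score,
   project onto PC1, bin into up to 10 equal-frequency strata, and draw
   the test fraction within each stratum (largest-remainder allocation),
   so the held-out set covers the class's principal spread. Classes with
   fewer than 7 rows fall back to a plain seeded split.

## Fuzzy C-means

Memberships and centers alternate as

    u_ij = 1 / Σ_c (d_ij / d_cj)^(2/(m−1)),
    v_i  = Σ_j u_ij^m x_j / Σ_j u_ij^m,

minimizing J = Σ_ij u_ij^m d_ij² until |ΔJ| < tol (1e-6) or 300
iterations. The fuzzifier default is m = 2; as m → 1⁺ assignments
approach k-means (checked against a k-means oracle from identical
initial centers). A point coincident with a center takes membership 1
there (limit convention). Initialization draws k distinct data points as
centers, with 5 seeded restarts keeping the lowest final J: initializing
from a random membership matrix instead would place every initial center
at the global mean, an exactly symmetric fixed point of the updates that
the iteration cannot escape in more than a few dimensions.

## Synthetic data

The generator emulates the statistical shape of a curated descriptor
table, not chemistry: class-conditional Gaussian features (negative mean
0, positive mean delta in pooled-SD units, applied to every feature),
mapped onto descriptor-like scales with a subset of columns rounded to
nonnegative integers so the integer-type invariants stay exercised.
Planted collinear columns are built as y = r·x_std + √(1−r²)·ε and
appended after their sources (so the documented greedy order removes
exactly the planted members). The positive class can be a mixture of
subpopulations with differing label-noise rates; a "noisy" row keeps its
positive label but draws its features from the negative distribution.
Subpopulation offsets are spread across all features with Euclidean
magnitude `subpop_separation` (default 6 pooled-SD) and ordered so
noisier subpopulations sit closer to the negative class — a single-axis
offset would be normalized away by the per-feature z-scoring of the
balancing stage. All randomness flows from the single spec seed.

Default study conditions: imbalance scenarios use n_pos = 300,
n_neg = 200 (ratio → k = 2) with two equal-weight subpopulations at
noise rates 0 and 0.3; the end-to-end checks use delta = 3 at n = 600
(signal) and delta = 0 at n = 400 over 20 seeds (noise floor). These
sizes keep the full property suite at desk scale while leaving the
separation/noise structure the analysis assumes intact. Passing on this
generator shows the machinery is correct under its stated assumptions —
Gaussian class-conditional structure, geometrically coherent
subpopulations — not that the descriptor panel separates real Pgp
classes; dataset-dependent performance is out of scope without the
original compound lists.

## Numerical choices and degenerate inputs

- Pessimistic pruning uses the standard upper confidence bound: exact
  binomial 1 − CF^(1/n) at zero observed errors, otherwise the normal
  approximation; a subtree is replaced when its bound is no better than
  the node-as-leaf bound.
- Constant descriptor columns correlate as 0 by definition (warned).
- Leaf class ties resolve to the lower class index; split ties as above.
- Duplicate retention keeps the first occurrence in input order, so a
  permuted input changes neither the census nor the removal reasons
  (only which representative survives).
- Reports are deterministic: no wall-clock timestamps enter
  `report.json`, provenance is (config hash, seed), and metric tables
  render at fixed 3 decimals.

## Known limitations

- Quantum descriptors require an external calculation; the Gasteiger
  Q_m surrogate is a labelled stand-in, not a replacement.
- The inducer makes binary numeric splits only (no categorical
  multiway splits) and no subtree raising during pruning.
- The PCA-stratified split is a documented realization of an
  under-specified sampling procedure; other realizations with the same
  coverage intent would give different (equally valid) partitions.
- No applicability-domain, y-scrambling or bootstrap validation, and no
  oversampling alternatives to cluster undersampling.
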