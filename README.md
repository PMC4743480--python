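# pgpcspr

A classification structure–property relationship (CSPR) pipeline for
P-glycoprotein (Pgp) screening. Pgp is an ATP-binding-cassette efflux
transporter central to multidrug resistance and drug pharmacokinetics;
predicting whether a compound inhibits it, or is transported by it, is a
standard early-ADMET question. This package implements the full workflow
for the two binary tasks (inhibitor vs. non-inhibitor, substrate vs.
non-substrate) as a tested, reusable library with a thin CLI, aimed at
cheminformaticians who want each stage inspectable and reproducible:

1. **Curation** — SMILES canonicalization, a 1000 Da molecular-weight
   filter, duplicate removal, and removal of compounds listed under more
   than one class, with a per-label census.
2. **Descriptors** — seven interpretable 2-D descriptors (MW, RBN, nCIC,
   nHDon, nHAcc, ALogP, TPSA) computed from structure; six quantum
   chemical descriptors (Q_m, energy, µ, HOMO, LUMO, HOMO–LUMO gap)
   merged from an external calculation and validated.
3. **Feature selection** — Pearson intercorrelation matrix with greedy
   removal of collinear descriptors at |r| ≥ 0.7.
4. **Imbalance correction** — fuzzy C-means splits the majority class
   into k = max(2, ⌈n_pos/n_neg⌉) clusters; each cluster ∪ negatives is
   scored by cross-validated decision-tree MCC and the best cluster
   becomes the representative positive set (undersampling by cluster
   selection).
5. **Models & validation** — a bespoke gain-ratio decision tree with
   extractable if-then rules, plus grid-searched MLP/SVM learners;
   accuracy, sensitivity, specificity and MCC

   - Acc = 100·(TP+TN)/N, Sens = 100·TP/(TP+FN), Spec = 100·TN/(TN+FP),
   - MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

   reported for training, pooled stratified 10-fold CV, and a
   PCA-stratified 85/15 external split.

Everything is exercisable on synthetic data with planted structure
(class separation, collinear columns, label-noise subpopulations), so no
external database is required; real compound lists are read from plain
CSV/TSV/SMI files.

## Worked example

Run the whole pipeline on a generated imbalanced scenario (300 positives
of which half carry 30 % label noise, 200 negatives, class separation 2
pooled-SD):

```toml
# example.toml
seed = 1
out_dir = "cspr_run"
task = "inhibitor"
learners = ["tree"]

[synthetic]
n_pos = 300
n_neg = 200
delta = 2.0
seed = 1

[[synthetic.pos_subpopulations]]
weight = 0.5
label_noise_rate = 0.0

[[synthetic.pos_subpopulations]]
weight = 0.5
label_noise_rate = 0.3
```

```
$ pgpcspr run-all --config example.toml
{"census": {"inhibitor": 300, "non_inhibitor": 200, "total": 500}, "models": ["tree"]}
```

`cspr_run/cluster_evaluation.csv` shows the performance-driven cluster
selection — the label-clean cluster wins by MCC and is kept as the
representative positive set:

```
cluster_id,size,cv,accuracy,sensitivity,specificity,mcc,selected
0,174,10-fold,99.198,100.000,98.500,0.984,True
1,126,10-fold,72.699,55.556,83.500,0.409,False
```

`cspr_run/metrics_tree.csv` is the four-statistic report of the final
tree on the balanced table (174 selected positives + 200 negatives):

```
,accuracy,sensitivity,specificity,mcc
training,99.371,100.000,98.824,0.987
cv,99.057,100.000,98.235,0.981
external,100.000,100.000,100.000,1.000
```

and `cspr_run/rules.txt` holds the tree as if-then rules, e.g.

```
  if f01 <= 630.192612762489 then non_inhibitor [n=168]
  if f01 > 630.192612762489 then inhibitor [n=150]
```

Here the noisy half of the positive class was discarded by cluster
selection, after which a single threshold on the first feature almost
perfectly separates the classes — the intended behavior on this planted
scenario, not a statement about real Pgp data.

The same stages are available as library calls (`curate`,
`build_feature_table`, `CollinearityPruner`, `FCMUnderSampler`,
`GainRatioTreeClassifier`, `kfold_cv`, …) and as individual subcommands
(`curate`, `describe`, `select-features`, `balance`, `train`,
`validate`, `simulate`). Estimators follow scikit-learn conventions
(`fit`/`predict`/`transform`, `get_params`, fitted attributes with a
trailing underscore) and compose with sklearn model selection.

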