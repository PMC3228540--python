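# onegene

Single-gene classifiers for two-class gene expression data.

Most expression-based cancer classifiers combine tens to thousands of genes,
which hurts interpretability and makes porting to clinical assay platforms
hard. `onegene` implements the opposite extreme — a classifier built on
**one** gene — together with the machinery needed to evaluate it honestly:

1. **Gene selection.** Score every gene with a two-sample test — pooled-variance
   t (SGC-t) or the Wilcoxon–Mann–Whitney rank-sum test (SGC-W, robust to
   gross errors) — and take the gene with the smallest p-value. Ties go to
   the smallest order number (row index in the source file).
2. **Cut point by entropy minimization.** Sort the training samples by the
   selected gene's expression E(g,s); candidate thresholds are the midpoints
   between adjacent samples of different class. Each candidate t splits the
   training set S into S1 = {s : E(g,s) ≤ t} and S2 = {s : E(g,s) > t}; with
   P_ij the intersections of S_i with the true classes C_1, C_2, the chosen
   cut point T minimizes the class information entropy

   E(g,t,S) = −(|S1|/|S|) Σ_j (|P1j|/|S1|) log2(|P1j|/|S1|)
              −(|S2|/|S|) Σ_j (|P2j|/|S2|) log2(|P2j|/|S2|)

   (0·log2 0 = 0). If no candidate exists (constant gene), T falls back to
   the mean expression.
3. **Direction rule.** The rule "E(g,s) ≤ T ⇒ c1, else c2" is kept if it
   classifies strictly more training samples correctly than incorrectly
   (|P11|+|P22| > |P12|+|P21|); otherwise — including the exact tie — the
   direction is reversed. Training accuracy is therefore ≥ 50% by
   construction.
4. **Complete leave-one-out cross-validation.** All of the above is redone
   from scratch inside every fold, so the held-out sample never influences
   development. Reports include overall accuracy, the mean number of genes
   per per-fold model, and each gene's occurrence percentage across the CV
   loop (selection stability). Stratified ~1:1 ("type 1") and ~2:1
   ("type 2") split-sample validation is also provided.

Standard comparators are included, each re-filtering genes at significance
level α = 0.001 inside every CV fold: diagonal linear discriminant analysis
(DLDA), 3-nearest neighbors, a linear-kernel SVM, a random forest (100
trees, √p candidate genes per split), and the classical top-scoring-pair
(TSP) rule. A dataset-characterization report (smallest p, largest fold
change, number of significant genes) summarizes how hard a dataset is, and
a seeded synthetic-data generator produces two-class Gaussian expression
matrices with known planted genes, Bayes-optimal cut points and optional
heavy-tailed contamination.

## Worked example

Simulate a dataset with one informative gene at a 3-SD shift
(per-gene Bayes accuracy Φ(3/2) ≈ 93.3%), train, and cross-validate:

```sh
onegene simulate --n1 20 --n2 20 --n-genes 500 --n-informative 1 \
    --effect-size 3.0 --seed 11 \
    --out-matrix expr.tsv --out-labels labels.tsv --out-truth truth.json
onegene train --matrix expr.tsv --labels labels.tsv --out model.json
onegene loocv --matrix expr.tsv --labels labels.tsv --out loocv.json
onegene characterize --matrix expr.tsv --labels labels.tsv --scale log2 \
    --out char.json
```

Output:

```
selected gene: g0361 (order 361)
cut point T:   7.73102
direction:     leq_is_c1
training accuracy: 97.5%

scheme: loocv
accuracy: 95.0%
mean genes per model: 1
stability (occurrence % across folds):
  g0361: 100.0%

smallest p-value:  3.63e-14 (g0361)
t-test statistic:  11.70
max fold change:   9.63 (g0361)
# significant genes at 0.001: 1
```

The planted gene (row 361, confirmed in `truth.json`) is selected in every
fold; LOOCV accuracy (95.0%) is close to the 93.3% Gaussian optimum — a
single-gene rule cannot beat the per-gene Bayes error, and complete LOOCV
keeps the estimate honest. `onegene compare` runs several classifiers under
one LOOCV and prints a combined accuracy / gene-count table; the same
operations are available as library functions (`train_sgc`, `loocv`,
`characterize`, ...).

Both a plain tab-delimited matrix + label file and the GCT v1.2 + CLS
dialect are supported; models and reports serialize to JSON.

## Layout

- `src/onegene/data.py`, `io.py` — dataset container, TSV and GCT/CLS round-trip
- `src/onegene/selection.py` — t / WMW scoring, ranking, significance filter
- `src/onegene/cutpoint.py` — candidate thresholds, entropy, direction rule
- `src/onegene/classifier.py` — train/predict/serialize the single-gene model
- `src/onegene/evaluation.py` — complete LOOCV, stratified splits, stability
- `src/onegene/characterization.py` — dataset difficulty report
- `src/onegene/comparators.py` — DLDA, 3-NN, linear SVM, RF, TSP
- `src/onegene/synthdata.py` — seeded generator with ground truth
- `src/onegene/cli.py` — `onegene` command with subcommands

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
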