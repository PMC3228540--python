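# Methods

## The model

`onegene` implements a hard-threshold classifier on a single gene for
two-class expression data. Development has three deterministic steps, all
performed on the training set only:

1. **Selection.** Each gene is scored by a two-sided two-sample test:
   pooled-variance t (default) or Wilcoxon–Mann–Whitney (WMW). Genes are
   ranked by ascending p-value; ties resolve to the smallest *order number*
   (0-based row index in the source file), which makes selection a total
   order and the whole pipeline reproducible bit-for-bit.
2. **Discretization.** For the selected gene, samples are sorted by
   expression (stable sort; original sample order breaks value ties).
   Candidate thresholds are the midpoints of adjacent different-class
   pairs. The threshold minimizing the weighted conditional class entropy
   (log base 2, 0·log 0 = 0) is the cut point T; entropy ties resolve to
   the smallest threshold.
3. **Orientation.** The rule "≤ T → c1" is kept only when it classifies
   strictly more training samples correctly than incorrectly; the exact
   tie reverses. This guarantees training accuracy ≥ 50%, with equality
   only in the tie case.

Class names are bound into the model at training time, with (c1, c2) taken
in lexicographic order of the two label strings. That convention (rather
than first appearance) makes every statistic invariant to sample order.

## Statistical details

- **t-test.** Pooled-variance by default (the classical two-sample form);
  Welch is available by flag. Degenerate genes follow a fixed convention:
  zero pooled variance (all values identical) gives p = 1 and is never
  selected ahead of any informative gene; per-class-constant values with
  different means are perfect separation, p = 0 with an infinite statistic
  signed by the mean difference.
- **WMW.** Mid-ranks for ties. The exact null distribution is used when
  the pooled sample is tie-free and has ≤ 20 observations (configurable);
  otherwise a normal approximation with tie correction and a 0.5
  continuity correction. Whole-matrix scoring is vectorized (ranking along
  the gene axis) because LOOCV re-scores every gene in every fold; the
  vectorized routine is tested for equality against
  `scipy.stats.mannwhitneyu` to 1e-12.
- **Sidedness.** All p-values are two-sided; selection by "most
  significant" is direction-free.
- **Significance filter.** `significant_genes` uses strict inequality
  (p < α). At the boundary α = 1 every non-degenerate gene qualifies.

## Candidate-set edge case

Taken literally, "midpoints of adjacent different-class pairs" always
yields at least one candidate when both classes are present — even for a
constant gene, where every midpoint equals the constant and the "≤ t"
partition puts *all* samples in S1. Such a cut induces no partition at
all: its entropy is the prior class entropy, which conditioning can never
exceed, so it can never be a strict minimizer. We therefore drop
candidates t ≥ max(expr). For a constant gene this empties the candidate
set and triggers the documented fallback (T = mean expression, which for a
constant gene is that constant); for the tied-but-informative case
(e.g. values 1,2,2,3 with the tie spanning the classes) the midpoint at
the shared value survives and, because the rule uses "≤ T", places all
tied samples on the low side.

## Symmetries, and where they break

Exact symmetries hold away from degenerate ties and are property-tested
with the corresponding guards:

- Label swap leaves T and entropy unchanged and flips the direction —
  *except* in the correct/incorrect tie, where the "≤ reverses" rule fires
  under both labelings and the direction is reversed in both.
- Strictly increasing transforms of the expressions induce the same
  training partition; negation yields identical training predictions when
  the entropy minimizer is unique and no sample sits exactly at the cut.
  With multiple minimizers the smallest-t tie-break picks mirror-image
  partitions, and tied-at-cut samples stay on the "≤" side under both
  orientations, so the literal invariants fail there by construction.

## Evaluation

**Complete LOOCV** repeats all development (selection, cut point,
orientation; for comparators, the α filter and fit) inside each fold.
There is no randomness in the fold structure. A fold that would leave a
class with fewer than two training samples is an error that advises
split-sample evaluation instead. Reports carry overall percent correct
(the headline metric), per-class accuracies (diagnostics), the mean panel
size per fold (`mean_genes_per_model`, exactly 1 for the single-gene
trainers), and each gene's occurrence percentage across folds.

**Split-sample validation** draws stratified random splits: the training
fraction is 1/2 (type 1) or 2/3 (type 2), rounded up within each class.
Stratification is our choice — the source procedure does not specify it —
because unstratified splits at typical study sizes can produce classless
test sets.

## Comparators

All four standard classifiers use only the genes significant at α = 0.001
in the current training set, re-computed per fold. When the filter is
empty the panel falls back to the single smallest-p gene (a classifier
needs a feature; the original behavior in this situation is unspecified,
and real panels as small as 2 genes occur).

- **DLDA** — per-gene class means, pooled per-gene variance; assign to the
  class minimizing Σ (x−μ)²/σ². Implemented directly (no library offers
  exactly the pooled-diagonal rule). Zero variances are floored at
  1e-8 × the gene's mean absolute expression; equidistant samples go
  to c1.
- **3-NN** — Euclidean distance, majority vote (scikit-learn). With two
  classes and k = 3 vote ties are impossible; distance ties follow the
  library's stable neighbor ordering.
- **Linear SVM** — soft margin, cost 1.0 by default (tuning it is reported
  to change little); scikit-learn `SVC(kernel="linear")`.
- **Random forest** — 100 trees, √p candidate features per split,
  majority vote; the only stochastic method, so a seed is mandatory.
- **TSP** — classical single top-scoring pair, no pre-filter. Primary
  score Δ_ij = |P̂(X_i<X_j|c1) − P̂(X_i<X_j|c2)|; ties break by the average
  within-sample rank-difference score, then smallest order numbers.
  Equal expressions count as "not <". O(p²) in the panel size, so use it
  on datasets of modest gene count or pre-reduced panels.

## Synthetic data

The generator emulates processed two-class expression matrices:
background genes i.i.d. Normal(μ0, σ0²) in both classes (defaults μ0 = 7,
σ0 = 1, log2-like units typical of processed arrays), informative genes
shifted in class 2 by δ·σ0 with δ configurable per gene, optional
contamination replacing a fraction (default 10%) of cells with draws at
10× the standard deviation (gross errors — the motivation for WMW
selection), optional linear scale (2^x, making shifts fold changes), and
configurable class sizes for imbalance. Ground truth records the planted
rows, the Bayes cut points (class-mean midpoints) and the per-gene Bayes
accuracy Φ(δ/2), so tests compare achieved accuracy to the optimum rather
than to arbitrary thresholds.

What it does **not** model: gene–gene correlation, per-gene baseline and
variance heterogeneity, batch effects, missing values. Passing tests show
the pipeline recovers planted univariate structure at realistic n and stays
calibrated under the null; they do not certify performance on correlated
real arrays.

## Problem sizes used in checks

The simulation-based checks run at study-condition sizes chosen once:
planted-gene recovery and LOOCV-vs-Bayes at δ = 3, n = 20 + 20, 1000
genes, 50 seeds; null calibration at n = 30 + 30, 500 genes, 50
label-permutation replicates; contamination robustness at the same sizes
with rate 0.1 and scale 10; the entropy-minimizer oracle on 1000 random
instances with n ≤ 12 (where exhaustive search is exact and instant).

## Numerical choices

- Cut points and midpoints are kept at full double precision; serialized
  values use 17 significant digits so round-trips are lossless.
- Entropy ties → smallest t; p-value ties → smallest order number;
  DLDA distance ties → c1; all documented above and deterministic.
- The WMW normal approximation clips p at 1.

## Known limitations

- Two classes only; no multi-class extension.
- No missing-value support: readers reject NA/empty cells outright.
- No multiple-testing correction — selection is by raw p-value rank, and
  the α = 0.001 comparator filter is used as-is, by design.
- Single cut point only; no recursive (multi-interval) discretization.
- Cut-point search is deliberately not part of gene selection: scanning
  thresholds for every gene would be far slower on array-sized data and
  discretization before selection can discard information.
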