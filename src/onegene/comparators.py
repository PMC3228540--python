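"""Standard comparison classifiers with per-training-set gene filtering.

Four baselines — diagonal linear discriminant analysis (DLDA), 3-nearest
neighbors, a linear-kernel soft-margin SVM, and a random forest with 100
trees sampling sqrt(p) genes per split — are each trained on the panel of
genes significant at level alpha (default 0.001) in the *current* training
set, so that wrapping them in LOOCV re-runs the filter inside every fold.
If the filter returns no genes, the single smallest-p gene is used as a
one-gene panel.  A fifth comparator, the classical top-scoring-pair (TSP)
rule, is rank-based and self-contained: it uses no pre-filter and decides
by the within-sample ordering of one gene pair.

k-NN, the SVM and the random forest delegate to scikit-learn; DLDA (the
pooled diagonal-covariance Gaussian rule) and TSP are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import ExpressionDataset
from .selection import score_all_genes, significant_genes

__all__ = [
    "ComparatorModel",
    "train_dlda",
    "train_knn",
    "train_svm_linear",
    "train_rf",
    "train_tsp",
    "filter_panel",
]

#: variance floor for DLDA, relative to a gene's mean absolute expression
DLDA_VAR_FLOOR = 1e-8


@dataclass
class ComparatorModel:
    """A fitted comparator over a filtered gene panel.

    ``gene_panel`` lists the gene ids that survived the alpha filter on the
    training set (selection order); ``panel_idx`` their row indices, used to
    extract features at prediction time.
    """

    kind: str
    gene_panel: list[str]
    panel_idx: list[int]
    classes: tuple[str, str]
    parameters: dict = field(default_factory=dict)
    _state: Any = None

    @property
    def selected_genes(self) -> list[str]:
        return list(self.gene_panel)

    @property
    def n_genes(self) -> int:
        return len(self.gene_panel)

    def _features(self, dataset: ExpressionDataset) -> np.ndarray:
        return dataset.values[self.panel_idx].T  # samples x panel genes

    def predict(self, dataset: ExpressionDataset) -> np.ndarray:
        x = self._features(dataset)
        if self.kind == "dlda":
            mu1, mu2, var = self._state
            d1 = np.sum((x - mu1) ** 2 / var, axis=1)
            d2 = np.sum((x - mu2) ** 2 / var, axis=1)
            # tie (equal distance) goes to c1
            return np.where(d1 <= d2, self.classes[0], self.classes[1]).astype(object)
        if self.kind == "tsp":
            i, j, c_low = self._state
            other = self.classes[1] if c_low == self.classes[0] else self.classes[0]
            xi = dataset.values[i]
            xj = dataset.values[j]
            return np.where(xi < xj, c_low, other).astype(object)
        return np.asarray(self._state.predict(x), dtype=object)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": "comparator",
            "kind": self.kind,
            "gene_panel": self.gene_panel,
            "classes": list(self.classes),
            "parameters": {k: v for k, v in self.parameters.items()},
        }


def filter_panel(dataset: ExpressionDataset, alpha: float,
                 method: str = "t") -> list:
    """Gene scores passing the alpha filter; falls back to the single
    smallest-p gene when the filter is empty (a classifier needs at least
    one feature)."""
    sig = significant_genes(dataset, alpha, method)
    if sig:
        return sig
    return [score_all_genes(dataset, method)[0]]


def _panel(dataset: ExpressionDataset, alpha: float):
    scores = filter_panel(dataset, alpha)
    return [s.gene_id for s in scores], [s.order_number for s in scores]


def train_dlda(dataset: ExpressionDataset, alpha: float = 0.001) -> ComparatorModel:
    """Diagonal linear discriminant analysis.

    Per-gene class means with a pooled per-gene variance; a sample is
    assigned to the class minimizing sum_g (x_g - mu_cg)^2 / sigma_g^2.
    Zero pooled variances are floored at a small epsilon relative to the
    gene's mean absolute expression.
    """
    dataset.require_training_sizes(2)
    ids, idx = _panel(dataset, alpha)
    mask1, mask2 = dataset.class_masks()
    x = dataset.values[idx]
    x1, x2 = x[:, mask1], x[:, mask2]
    mu1 = x1.mean(axis=1)
    mu2 = x2.mean(axis=1)
    n1, n2 = x1.shape[1], x2.shape[1]
    pooled = ((n1 - 1) * x1.var(axis=1, ddof=1)
              + (n2 - 1) * x2.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    floor = DLDA_VAR_FLOOR * np.maximum(np.abs(x).mean(axis=1), 1.0)
    if np.any(pooled < floor):
        warnings.warn("DLDA: zero/near-zero pooled variance floored")
        pooled = np.maximum(pooled, floor)
    return ComparatorModel("dlda", ids, idx, dataset.classes,
                           {"alpha": alpha}, (mu1, mu2, pooled))


def train_knn(dataset: ExpressionDataset, alpha: float = 0.001,
              k: int = 3) -> ComparatorModel:
    """k-nearest neighbors (Euclidean distance, majority vote) on the
    filtered panel.  If fewer training samples than k exist, all are used."""
    dataset.require_training_sizes(2)
    ids, idx = _panel(dataset, alpha)
    k_eff = min(k, dataset.n_samples)
    est = KNeighborsClassifier(n_neighbors=k_eff, metric="euclidean")
    est.fit(dataset.values[idx].T, [str(v) for v in dataset.labels])
    return ComparatorModel("knn", ids, idx, dataset.classes,
                           {"alpha": alpha, "k": k_eff}, est)


def train_svm_linear(dataset: ExpressionDataset, alpha: float = 0.001,
                     cost: float = 1.0) -> ComparatorModel:
    """Soft-margin SVM with the linear inner-product kernel."""
    dataset.require_training_sizes(2)
    ids, idx = _panel(dataset, alpha)
    est = SVC(kernel="linear", C=cost)
    est.fit(dataset.values[idx].T, [str(v) for v in dataset.labels])
    return ComparatorModel("svm_linear", ids, idx, dataset.classes,
                           {"alpha": alpha, "cost": cost}, est)


def train_rf(dataset: ExpressionDataset, alpha: float = 0.001,
             n_trees: int = 100, seed: int = 0) -> ComparatorModel:
    """Random forest: ``n_trees`` trees, sqrt(panel size) candidate genes
    per split, majority vote.  The only stochastic comparator; the seed is
    mandatory for reproducibility."""
    dataset.require_training_sizes(2)
    ids, idx = _panel(dataset, alpha)
    est = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 random_state=seed)
    est.fit(dataset.values[idx].T, [str(v) for v in dataset.labels])
    return ComparatorModel("rf", ids, idx, dataset.classes,
                           {"alpha": alpha, "n_trees": n_trees, "seed": seed},
                           est)


def tsp_pair_scores(values: np.ndarray, mask1: np.ndarray,
                    mask2: np.ndarray) -> dict[tuple[int, int], float]:
    """Primary TSP score for every gene pair (i < j).

    Delta_ij = | P(X_i < X_j | c1) - P(X_i < X_j | c2) | estimated by
    within-class frequencies.
    """
    p = values.shape[0]
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(p), 2):
        f1 = float(np.mean(values[i, mask1] < values[j, mask1]))
        f2 = float(np.mean(values[i, mask2] < values[j, mask2]))
        out[(i, j)] = abs(f1 - f2)
    return out


def _tsp_secondary(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray,
                   i: int, j: int) -> float:
    """Average within-sample rank-difference score, for primary-score ties."""
    ranks = rankdata(values, axis=0)  # rank of each gene within each sample
    d = ranks[i] - ranks[j]
    return abs(float(d[mask1].mean()) - float(d[mask2].mean()))


def train_tsp(dataset: ExpressionDataset) -> ComparatorModel:
    """Classical single top-scoring-pair classifier.

    Rank-based and self-contained: no gene pre-filter.  Ties in the primary
    score break by the secondary rank score, then by smallest order numbers.
    Prediction follows the majority orientation of the winning pair in the
    training set.
    """
    dataset.require_training_sizes(2)
    if dataset.n_genes < 2:
        raise ValueError("TSP requires at least two genes")
    mask1, mask2 = dataset.class_masks()
    scores = tsp_pair_scores(dataset.values, mask1, mask2)
    best = max(scores.values())
    if best == 0.0:
        raise ValueError("no discriminative pair: all pair scores are zero")
    tied = sorted(k for k, v in scores.items() if v == best)
    if len(tied) > 1:
        sec = [_tsp_secondary(dataset.values, mask1, mask2, i, j)
               for i, j in tied]
        best_sec = max(sec)
        tied = [k for k, s in zip(tied, sec) if s == best_sec]
    i, j = tied[0]  # smallest order numbers among remaining ties
    c1, c2 = dataset.classes
    f1 = float(np.mean(dataset.values[i, mask1] < dataset.values[j, mask1]))
    f2 = float(np.mean(dataset.values[i, mask2] < dataset.values[j, mask2]))
    c_low = c1 if f1 > f2 else c2  # class predicted when X_i < X_j
    return ComparatorModel(
        "tsp", [dataset.gene_ids[i], dataset.gene_ids[j]], [i, j],
        (c1, c2), {"delta": best, "pair": [i, j]}, (i, j, c_low))
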