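"""Classifier performance estimation.

Complete leave-one-out cross-validation repeats *all* of classifier
development — gene selection, cut-point search, rule orientation, or a
comparator's significance filter and fit — inside every fold, so the held
out sample never influences development.  Split-sample validation offers
the two train:test ratios in common use (~1:1 and ~2:1), stratified by
class.  Reports carry overall accuracy, the mean number of genes per
per-fold model, and the stability (occurrence percentage) of each selected
gene across the CV loop.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import DatasetError, ExpressionDataset

__all__ = [
    "FoldRecord",
    "EvaluationResult",
    "loocv",
    "split_sample",
    "evaluate_split",
    "gene_stability",
]

REPORT_SCHEMA_VERSION = 1

#: a trainer maps a training dataset to a fitted model exposing
#: ``predict(dataset) -> labels`` and ``selected_genes``/``n_genes``.
Trainer = Callable[[ExpressionDataset], object]


@dataclass
class FoldRecord:
    held_out: list[str]
    selected_genes: list[str]
    n_genes: int
    model_summary: dict
    predicted: list[str]
    truth: list[str]


@dataclass
class EvaluationResult:
    scheme: str
    per_fold: list[FoldRecord]
    accuracy_pct: float
    mean_genes_per_model: float
    stability: dict[str, float]
    per_class_accuracy_pct: dict[str, float]
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "scheme": self.scheme,
            "seed": self.seed,
            "accuracy_pct": self.accuracy_pct,
            "mean_genes_per_model": self.mean_genes_per_model,
            "per_class_accuracy_pct": self.per_class_accuracy_pct,
            "stability": [
                {"gene_id": g, "occurrence_pct": p}
                for g, p in self.stability.items()
            ],
            "folds": [
                {
                    "held_out": f.held_out,
                    "selected_genes": f.selected_genes,
                    "n_genes": f.n_genes,
                    "model": f.model_summary,
                    "predicted": f.predicted,
                    "truth": f.truth,
                }
                for f in self.per_fold
            ],
            "metadata": self.metadata,
        }

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)

    def summary_text(self) -> str:
        lines = [
            f"scheme: {self.scheme}",
            f"accuracy: {self.accuracy_pct:.1f}%",
            f"mean genes per model: {self.mean_genes_per_model:g}",
            "stability (occurrence % across folds):",
        ]
        for g, p in self.stability.items():
            lines.append(f"  {g}: {p:.1f}%")
        return "\n".join(lines)


def _model_summary(model: object) -> dict:
    if hasattr(model, "to_dict"):
        d = model.to_dict()
        d.pop("training_stats", None)
        return d
    return {"kind": getattr(model, "kind", type(model).__name__)}


def _model_genes(model: object) -> list[str]:
    genes = getattr(model, "selected_genes", None)
    if genes is None:
        raise TypeError("trainer result must expose 'selected_genes'")
    return list(genes)


def _aggregate(scheme: str, folds: list[FoldRecord],
               seed: int | None, metadata: dict) -> EvaluationResult:
    predicted = [p for f in folds for p in f.predicted]
    truth = [t for f in folds for t in f.truth]
    correct = sum(p == t for p, t in zip(predicted, truth))
    accuracy = 100.0 * correct / len(truth)
    per_class: dict[str, float] = {}
    for cls in sorted(set(truth)):
        idx = [i for i, t in enumerate(truth) if t == cls]
        per_class[cls] = 100.0 * sum(predicted[i] == truth[i] for i in idx) / len(idx)
    counts = Counter(g for f in folds for g in set(f.selected_genes))
    stability = {
        g: 100.0 * c / len(folds)
        for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    mean_genes = float(np.mean([f.n_genes for f in folds]))
    return EvaluationResult(scheme, folds, accuracy, mean_genes, stability,
                            per_class, seed, metadata)


def loocv(dataset: ExpressionDataset, trainer: Trainer) -> EvaluationResult:
    """Complete leave-one-out cross-validation.

    Each sample is held out once; the trainer redevelops the classifier on
    the remaining n-1 samples (no leakage) and predicts the held-out sample.
    Deterministic given a deterministic trainer — there is no randomness in
    the fold structure, so ``seed`` is recorded as None.
    """
    n = dataset.n_samples
    lab = np.array([str(v) for v in dataset.labels])
    for cls, count in Counter(lab).items():
        if count - 1 < 2:
            raise DatasetError(
                f"leaving out one sample drops class {cls!r} below 2 training "
                "samples; use split-sample evaluation instead"
            )
    folds: list[FoldRecord] = []
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        model = trainer(dataset.subset_samples(train_idx))
        pred = model.predict(dataset.subset_samples([i]))
        genes = _model_genes(model)
        folds.append(FoldRecord(
            held_out=[dataset.sample_ids[i]],
            selected_genes=genes,
            n_genes=int(getattr(model, "n_genes", len(genes))),
            model_summary=_model_summary(model),
            predicted=[str(pred[0])],
            truth=[lab[i]],
        ))
    return _aggregate("loocv", folds, None, {"n_samples": n})


def split_sample(dataset: ExpressionDataset, split_type: str,
                 seed: int) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified random train/test split.

    ``type1`` puts about half the samples in training, ``type2`` about two
    thirds; within each class the training share is rounded up.  The split
    is a pure function of (dataset, split_type, seed).
    """
    fractions = {"type1": 0.5, "type2": 2.0 / 3.0}
    if split_type not in fractions:
        raise ValueError(f"split_type must be 'type1' or 'type2', got {split_type!r}")
    frac = fractions[split_type]
    rng = np.random.default_rng(seed)
    lab = np.array([str(v) for v in dataset.labels])
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(lab)):
        members = np.flatnonzero(lab == cls)
        n_train = int(np.ceil(frac * members.size))
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    train_ds = dataset.subset_samples(train_idx)
    test_ds = dataset.subset_samples(test_idx)
    for part, name in ((train_ds, "training"), (test_ds, "test")):
        counts = Counter(str(v) for v in part.labels)
        if len(counts) < 2 or min(counts.values()) < 2:
            raise DatasetError(
                f"{split_type} split leaves a class with < 2 samples in the "
                f"{name} set; dataset too small for this scheme"
            )
    return train_ds, test_ds


def evaluate_split(train_dataset: ExpressionDataset,
                   test_dataset: ExpressionDataset,
                   trainer: Trainer, *, scheme: str = "split",
                   seed: int | None = None) -> EvaluationResult:
    """Train once on the training set, measure accuracy on the test set."""
    if train_dataset.gene_ids != test_dataset.gene_ids:
        raise DatasetError("train and test sets must share the same gene panel")
    model = trainer(train_dataset)
    pred = model.predict(test_dataset)
    genes = _model_genes(model)
    fold = FoldRecord(
        held_out=list(test_dataset.sample_ids),
        selected_genes=genes,
        n_genes=int(getattr(model, "n_genes", len(genes))),
        model_summary=_model_summary(model),
        predicted=[str(p) for p in pred],
        truth=[str(t) for t in test_dataset.labels],
    )
    return _aggregate(scheme, [fold], seed,
                      {"n_train": train_dataset.n_samples,
                       "n_test": test_dataset.n_samples})


def gene_stability(result: EvaluationResult) -> dict[str, float]:
    """Occurrence percentage of each selected gene across CV folds,
    descending.  For single-gene trainers the percentages sum to 100."""
    return dict(result.stability)
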