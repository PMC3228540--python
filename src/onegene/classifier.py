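"""Train/predict interface for the single-gene classifier (SGC-t, SGC-W).

Training composes the three development steps — pick the most significant
gene, find its entropy-optimal cut point, orient the rule — on the training
set.  The resulting model depends only on one gene's expression, the
threshold T and the direction, and serializes losslessly to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cutpoint import LEQ_IS_C1, optimal_cut_point
from .data import ExpressionDataset
from .selection import select_top_gene

__all__ = ["SingleGeneClassifier", "train_sgc", "predict"]

SCHEMA_VERSION = 1


@dataclass
class SingleGeneClassifier:
    """A hard-threshold rule on one gene.

    ``classes`` is the (c1, c2) pair the model was trained with; predictions
    return these names, so output is label-stable regardless of how a later
    input encodes its own labels.
    """

    gene_id: str
    order_number: int
    method: str
    cut_point: float
    direction: str
    classes: tuple[str, str]
    training_stats: dict = field(default_factory=dict)

    @property
    def selected_genes(self) -> list[str]:
        return [self.gene_id]

    @property
    def n_genes(self) -> int:
        return 1

    # -- prediction --------------------------------------------------------

    def predict(self, data: ExpressionDataset | np.ndarray) -> np.ndarray:
        """Class labels for a dataset (gene looked up by id) or a raw
        expression vector of the model's gene."""
        if isinstance(data, ExpressionDataset):
            try:
                row = data.gene_index(self.gene_id)
            except KeyError:
                raise KeyError(
                    f"model gene {self.gene_id!r} missing from input dataset"
                ) from None
            expr = data.values[row]
        else:
            expr = np.asarray(data, dtype=float)
        c_leq, c_gt = ((self.classes[0], self.classes[1])
                       if self.direction == LEQ_IS_C1
                       else (self.classes[1], self.classes[0]))
        return np.where(expr <= self.cut_point, c_leq, c_gt).astype(object)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model": "single_gene_classifier",
            "method": self.method,
            "gene_id": self.gene_id,
            "order_number": self.order_number,
            "cut_point": self.cut_point,
            "direction": self.direction,
            "classes": list(self.classes),
            "training_stats": self.training_stats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SingleGeneClassifier":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {d.get('schema_version')}")
        return cls(
            gene_id=d["gene_id"],
            order_number=int(d["order_number"]),
            method=d["method"],
            cut_point=float(d["cut_point"]),
            direction=d["direction"],
            classes=(d["classes"][0], d["classes"][1]),
            training_stats=dict(d.get("training_stats", {})),
        )

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "SingleGeneClassifier":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def train_sgc(dataset: ExpressionDataset, method: str = "t",
              **score_kwargs) -> SingleGeneClassifier:
    """Develop a single-gene classifier on a training set.

    Deterministic.  By construction of the direction rule the model's
    training accuracy is at least 50% (strictly above unless the
    correct/incorrect tie occurred).
    """
    dataset.require_training_sizes(2)
    top = select_top_gene(dataset, method, **score_kwargs)
    expr = dataset.values[top.order_number]
    classes = dataset.classes
    cut = optimal_cut_point(expr, dataset.labels, classes)
    n1, n2 = dataset.class_sizes()
    return SingleGeneClassifier(
        gene_id=top.gene_id,
        order_number=top.order_number,
        method=method,
        cut_point=cut.T,
        direction=cut.direction,
        classes=classes,
        training_stats={
            "statistic": top.statistic,
            "p_value": top.p_value,
            "entropy": cut.entropy,
            "fallback_used": cut.fallback_used,
            "candidate_count": cut.candidate_count,
            "n1": n1,
            "n2": n2,
        },
    )


def predict(model: SingleGeneClassifier,
            data: ExpressionDataset | np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`SingleGeneClassifier.predict`."""
    return model.predict(data)
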