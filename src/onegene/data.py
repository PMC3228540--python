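"""Core containers for two-class gene expression data.

An :class:`ExpressionDataset` holds a genes x samples matrix together with
gene identifiers (whose row index is the gene's *order number*, used to break
p-value ties deterministically), sample identifiers and a binary class label
per sample.  Expression values are stored exactly as supplied — linear or
log scale — with the scale recorded in ``metadata`` and never transformed
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ExpressionDataset", "ClassPartition", "DatasetError"]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with binary class labels.

    Parameters
    ----------
    gene_ids
        Gene identifiers in file row order.  Duplicates are permitted (common
        on arrays); a gene's identity is the pair (id, order number) where the
        order number is its 0-based row index.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
    labels
        One class name per sample; exactly two distinct names must occur.
    metadata
        Free-form provenance (source paths, expression scale, ...).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise DatasetError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.labels.shape != (len(self.sample_ids),):
            raise DatasetError("one class label required per sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DatasetError("sample ids must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DatasetError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        uniq = sorted({str(c) for c in self.labels})
        # a prediction-only subset may hold a single class; training
        # contexts enforce two classes via require_training_sizes()
        if len(uniq) > 2:
            raise DatasetError(
                f"at most two classes allowed, found {len(uniq)}: {uniq}"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> tuple[str, str]:
        """The two class names (c1, c2) in lexicographic order.

        Lexicographic ordering makes every downstream statistic invariant to
        sample order, which first-appearance ordering would not be.
        """
        c = sorted({str(v) for v in self.labels})
        if len(c) != 2:
            raise DatasetError("dataset does not contain two classes")
        return (c[0], c[1])

    def class_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (class-1 samples, class-2 samples)."""
        c1, c2 = self.classes
        lab = np.array([str(v) for v in self.labels])
        return lab == c1, lab == c2

    def class_sizes(self) -> tuple[int, int]:
        m1, m2 = self.class_masks()
        return int(m1.sum()), int(m2.sum())

    def require_training_sizes(self, min_per_class: int = 2) -> None:
        n1, n2 = self.class_sizes()
        if n1 < min_per_class or n2 < min_per_class:
            raise DatasetError(
                f"each class needs >= {min_per_class} samples for training "
                f"(found {n1} and {n2})"
            )

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given sample indices (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels[idx],
            metadata=dict(self.metadata),
        )

    def gene_index(self, gene_id: str) -> int:
        """Row index of the first gene with this id.

        Raises
        ------
        KeyError
            If the gene id is absent.
        """
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in dataset") from None


@dataclass(frozen=True)
class ClassPartition:
    """The 2x2 cross-tabulation of a threshold partition against true classes.

    ``S1``/``S2`` are the sample index sets at or below / above the threshold;
    ``p11, p12, p21, p22`` count their intersections with the true classes
    C1 and C2 (``p12`` = class-2 samples falling in S1, etc.).
    """

    s1: tuple[int, ...]
    s2: tuple[int, ...]
    p11: int
    p12: int
    p21: int
    p22: int

    def __post_init__(self) -> None:
        if self.p11 + self.p12 != len(self.s1) or self.p21 + self.p22 != len(self.s2):
            raise ValueError("partition counts inconsistent with index sets")

    @property
    def n(self) -> int:
        return len(self.s1) + len(self.s2)


def partition_at(expr: np.ndarray, labels: np.ndarray, t: float,
                 classes: tuple[str, str]) -> ClassPartition:
    """Cross-tabulate the partition {expr <= t} / {expr > t} against classes."""
    expr = np.asarray(expr, dtype=float)
    lab = np.array([str(v) for v in labels])
    c1 = lab == classes[0]
    low = expr <= t
    return ClassPartition(
        s1=tuple(np.flatnonzero(low)),
        s2=tuple(np.flatnonzero(~low)),
        p11=int(np.sum(low & c1)),
        p12=int(np.sum(low & ~c1)),
        p21=int(np.sum(~low & c1)),
        p22=int(np.sum(~low & ~c1)),
    )
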