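"""Dataset difficulty statistics.

Summarizes how hard a two-class expression dataset is to classify: the
smallest univariate t-test p-value and its t-statistic, the largest
between-class mean fold change, and the number of genes significant at a
given level (default 0.001).  Large fold changes and many significant genes
mark the "easy" regime where even a single gene classifies well.

Fold change is computed on the linear scale, oriented >= 1 (larger class
mean over smaller); ``scale_flag='log2'`` unlogs the values first.  Genes
whose linear-scale class means are not both positive have no meaningful
ratio and are excluded from the fold-change ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .selection import score_all_genes, significant_genes

__all__ = ["CharacterizationReport", "characterize"]


@dataclass
class CharacterizationReport:
    smallest_p: float
    t_at_smallest_p: float       # absolute value, sign kept separately
    t_sign: int
    top_gene_id: str
    max_fold_change: float
    max_fold_change_gene: str | None
    n_significant: int
    alpha: float
    scale_flag: str
    n_genes: int
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "smallest_p": self.smallest_p,
            "t_statistic_abs": self.t_at_smallest_p,
            "t_statistic_sign": self.t_sign,
            "top_gene_id": self.top_gene_id,
            "max_fold_change": self.max_fold_change,
            "max_fold_change_gene": self.max_fold_change_gene,
            "n_significant": self.n_significant,
            "alpha": self.alpha,
            "scale_flag": self.scale_flag,
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
        }

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_text(self) -> str:
        return "\n".join([
            f"smallest p-value:  {self.smallest_p:.3g} ({self.top_gene_id})",
            f"t-test statistic:  {self.t_at_smallest_p:.2f}",
            f"max fold change:   {self.max_fold_change:.2f}"
            + (f" ({self.max_fold_change_gene})" if self.max_fold_change_gene else ""),
            f"# significant genes at {self.alpha:g}: {self.n_significant}",
        ])


def characterize(dataset: ExpressionDataset, alpha: float = 0.001,
                 scale_flag: str = "linear") -> CharacterizationReport:
    """Compute the difficulty statistics of a dataset."""
    if scale_flag not in ("linear", "log2"):
        raise ValueError(f"scale_flag must be 'linear' or 'log2', got {scale_flag!r}")
    scores = score_all_genes(dataset, "t")
    top = scores[0]
    n_sig = len(significant_genes(dataset, alpha, "t"))

    mask1, mask2 = dataset.class_masks()
    vals = dataset.values
    if scale_flag == "log2":
        vals = np.exp2(vals)
    m1 = vals[:, mask1].mean(axis=1)
    m2 = vals[:, mask2].mean(axis=1)
    valid = (m1 > 0) & (m2 > 0)
    n_excluded = int(np.sum(~valid))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} gene(s) with non-positive linear-scale class mean "
            "excluded from fold-change ranking"
        )
    if np.any(valid):
        fc = np.where(m1[valid] >= m2[valid], m1[valid] / m2[valid],
                      m2[valid] / m1[valid])
        best = int(np.argmax(fc))
        max_fc = float(fc[best])
        fc_gene = dataset.gene_ids[int(np.flatnonzero(valid)[best])]
    else:
        max_fc, fc_gene = float("nan"), None

    return CharacterizationReport(
        smallest_p=top.p_value,
        t_at_smallest_p=abs(top.statistic),
        t_sign=int(np.sign(top.statistic)),
        top_gene_id=top.gene_id,
        max_fold_change=max_fc,
        max_fold_change_gene=fc_gene,
        n_significant=n_sig,
        alpha=alpha,
        scale_flag=scale_flag,
        n_genes=dataset.n_genes,
        n_samples=dataset.n_samples,
    )
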