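"""Univariate per-gene statistics and top-gene selection.

Genes are scored one at a time by a two-sample test — pooled-variance t by
default (Welch available), or the Wilcoxon-Mann-Whitney (WMW) rank-sum test
— and ranked by ascending p-value with ties broken by the gene's *order
number* (row index in the source file), smallest first.  The WMW test is the
robust alternative: being rank-based it is insensitive to gross errors and
heavy-tailed contamination that can mislead the t-test.

Scoring an entire matrix is vectorized: the t path uses
``scipy.stats.ttest_ind`` over the gene axis, and the WMW
normal-approximation path is an in-package vectorized routine (mid-ranks,
tie correction, continuity correction) that agrees with
``scipy.stats.mannwhitneyu`` to floating-point accuracy; the exact WMW null
distribution is used for small tie-free genes (total n <= 20 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionDataset

__all__ = [
    "GeneScore",
    "t_score",
    "wmw_score",
    "score_all_genes",
    "select_top_gene",
    "significant_genes",
    "NoInformativeGeneError",
]

#: genes with pooled sample size at or below this use the exact WMW null
#: distribution (when tie-free); larger genes use the normal approximation.
WMW_EXACT_MAX_N = 20


class NoInformativeGeneError(ValueError):
    """All genes are degenerate (constant across all samples)."""


@dataclass(frozen=True)
class GeneScore:
    """Univariate score of one gene.

    ``degenerate`` marks a gene whose pooled values are all identical, for
    which no test statistic exists; such genes get p = 1 by convention and
    are never selected ahead of any informative gene.
    """

    gene_id: str
    order_number: int
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False

    @property
    def sort_key(self) -> tuple[float, int]:
        return (self.p_value, self.order_number)


# ---------------------------------------------------------------------------
# scalar tests


def t_score(x1, x2, equal_var: bool = True) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test.

    Returns ``(statistic, p_value, degenerate)``.  Pooled-variance by
    default; ``equal_var=False`` gives the Welch form.  Degenerate inputs
    follow a fixed convention: if the pooled sample has zero variance the
    gene carries no information, so (0, 1, True); if each group is constant
    but the means differ the separation is perfect, so p = 0 with an
    infinite statistic signed by the mean difference.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs >= 2 values")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        diff = x1.mean() - x2.mean()
        if diff == 0.0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, diff), 0.0, True
    res = stats.ttest_ind(x1, x2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), False


def _wmw_normal_approx(u1: float, n1: int, n2: int,
                       tie_term: float) -> float:
    """Two-sided p for U1 under the tie-corrected normal approximation.

    ``tie_term`` is sum(t^3 - t) over tied groups of the pooled sample.
    Uses a 0.5 continuity correction toward the mean.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0.0:
        return 1.0
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wmw_score(x1, x2, exact_max_n: int = WMW_EXACT_MAX_N
              ) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Returns ``(U1, p_value, degenerate)`` where ``U1`` is the
    Mann-Whitney U statistic of the first group.  The exact null
    distribution is used when the pooled sample is tie-free and no larger
    than ``exact_max_n``; otherwise the normal approximation with mid-ranks,
    tie correction and continuity correction.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs >= 2 values")
    n1, n2 = x1.size, x2.size
    pooled = np.concatenate([x1, x2])
    uniq, counts = np.unique(pooled, return_counts=True)
    if uniq.size == 1:
        return float(n1 * n2 / 2.0), 1.0, True
    has_ties = np.any(counts > 1)
    if n1 + n2 <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                                 method="exact")
        return float(res.statistic), float(res.pvalue), False
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return u1, _wmw_normal_approx(u1, n1, n2, tie_term), False


# ---------------------------------------------------------------------------
# matrix scoring


def _t_scores_matrix(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray,
                     equal_var: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x1, x2 = values[:, mask1], values[:, mask2]
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            _warnings.catch_warnings():
        # constant rows trigger scipy precision warnings; their results are
        # replaced by the degenerate-gene convention below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x1, x2, axis=1, equal_var=equal_var)
        stat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    degen = (x1.var(axis=1, ddof=1) == 0.0) & (x2.var(axis=1, ddof=1) == 0.0)
    if np.any(degen):
        diff = x1.mean(axis=1) - x2.mean(axis=1)
        zero = degen & (diff == 0.0)
        sep = degen & (diff != 0.0)
        stat[zero], p[zero] = 0.0, 1.0
        stat[sep] = np.sign(diff[sep]) * np.inf
        p[sep] = 0.0
    return stat, p, degen & (p == 1.0)


def _wmw_scores_matrix(values: np.ndarray, mask1: np.ndarray,
                       mask2: np.ndarray, exact_max_n: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    n = n1 + n2
    ordered = np.concatenate([values[:, mask1], values[:, mask2]], axis=1)
    ranks = stats.rankdata(ordered, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    srt = np.sort(ordered, axis=1)
    new_val = np.ones_like(srt, dtype=bool)
    new_val[:, 1:] = srt[:, 1:] != srt[:, :-1]
    # run lengths of tied groups per gene, via positions of value changes
    tie_term = np.empty(values.shape[0])
    has_ties = np.empty(values.shape[0], dtype=bool)
    for g in range(values.shape[0]):
        counts = np.diff(np.append(np.flatnonzero(new_val[g]), n)).astype(float)
        tie_term[g] = np.sum(counts ** 3 - counts)
        has_ties[g] = np.any(counts > 1)

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    degen = var <= 0.0
    z = np.zeros_like(u1)
    good = ~degen
    z[good] = (u1[good] - mu - 0.5 * np.sign(u1[good] - mu)) / np.sqrt(var[good])
    p = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p[degen] = 1.0
    if n <= exact_max_n:
        for g in np.flatnonzero(~has_ties):
            res = stats.mannwhitneyu(ordered[g, :n1], ordered[g, n1:],
                                     alternative="two-sided", method="exact")
            u1[g], p[g] = float(res.statistic), float(res.pvalue)
    return u1, p, degen


def score_all_genes(dataset: ExpressionDataset, method: str = "t", *,
                    equal_var: bool = True,
                    exact_max_n: int = WMW_EXACT_MAX_N) -> list[GeneScore]:
    """Score every gene; result sorted by (p-value, order number) ascending.

    The ordering is a total order and the computation is deterministic, so
    repeated calls are bit-identical.
    """
    if method not in ("t", "wmw"):
        raise ValueError(f"unknown method {method!r} (expected 't' or 'wmw')")
    dataset.require_training_sizes(2)
    mask1, mask2 = dataset.class_masks()
    if method == "t":
        stat, p, degen = _t_scores_matrix(dataset.values, mask1, mask2,
                                          equal_var)
    else:
        stat, p, degen = _wmw_scores_matrix(dataset.values, mask1, mask2,
                                            exact_max_n)
    scores = [
        GeneScore(dataset.gene_ids[i], i, float(stat[i]), float(p[i]),
                  method, bool(degen[i]))
        for i in range(dataset.n_genes)
    ]
    scores.sort(key=lambda s: s.sort_key)
    return scores


def select_top_gene(dataset: ExpressionDataset, method: str = "t",
                    **kwargs) -> GeneScore:
    """The single most significant gene; ties go to the smallest order number.

    Raises
    ------
    NoInformativeGeneError
        If every gene is degenerate (constant expression).
    """
    scores = score_all_genes(dataset, method, **kwargs)
    top = scores[0]
    if top.degenerate:
        raise NoInformativeGeneError(
            "no informative gene: all genes constant across samples"
        )
    return top


def significant_genes(dataset: ExpressionDataset, alpha: float,
                      method: str = "t", **kwargs) -> list[GeneScore]:
    """Genes with p strictly below ``alpha``, in selection order."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    scores = score_all_genes(dataset, method, **kwargs)
    if alpha == 1.0:  # boundary: every testable gene qualifies
        return [s for s in scores if not s.degenerate]
    return [s for s in scores if s.p_value < alpha and not s.degenerate]
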