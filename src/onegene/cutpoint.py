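"""Entropy-based optimal cut point and the direction/reversal rule.

Given one gene's expression across a labelled training set, the samples are
sorted by expression and every midpoint between adjacent samples of
*different* class becomes a candidate threshold.  Each candidate t splits
the set into S1 = {expression <= t} and S2 = {expression > t}; the candidate
minimizing the class information entropy

    E(t) = -|S1|/|S| * sum_c (|S1 ∩ C_c|/|S1|) log2(|S1 ∩ C_c|/|S1|)
           -|S2|/|S| * sum_c (|S2 ∩ C_c|/|S2|) log2(|S2 ∩ C_c|/|S2|)

(with 0·log2 0 = 0) is the optimal cut point T.  If no adjacent pair of
sorted samples differs in class — possible only when the gene is constant —
the candidate set is empty and T falls back to the mean expression.

The decision rule "expression <= T -> class c1, > T -> c2" is kept when it
classifies strictly more training samples correctly than incorrectly;
otherwise (including the exact tie) the direction is reversed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import partition_at

__all__ = [
    "CutPointResult",
    "candidate_cut_points",
    "partition_entropy",
    "optimal_cut_point",
    "rule_direction",
    "LEQ_IS_C1",
    "LEQ_IS_C2",
]

LEQ_IS_C1 = "leq_is_c1"
LEQ_IS_C2 = "leq_is_c2"


@dataclass(frozen=True)
class CutPointResult:
    """Optimal threshold for one gene on one training set."""

    T: float
    entropy: float
    direction: str
    candidate_count: int
    fallback_used: bool


def _canonical_order(expr: np.ndarray) -> np.ndarray:
    """Ascending sort with original sample order breaking ties (stable)."""
    return np.argsort(expr, kind="stable")


def candidate_cut_points(expr, labels) -> np.ndarray:
    """Midpoints between adjacent sorted samples of different class.

    Sorted ascending, duplicates removed.  May be empty (only when the gene
    cannot separate any adjacent pair under the canonical tie ordering, e.g.
    all values identical).
    """
    expr = np.asarray(expr, dtype=float)
    lab = np.array([str(v) for v in labels])
    order = _canonical_order(expr)
    e, c = expr[order], lab[order]
    boundary = c[:-1] != c[1:]
    mids = np.unique((e[:-1][boundary] + e[1:][boundary]) / 2.0)
    # a midpoint at or above the maximum (possible only through ties) puts
    # every sample in S1 and induces no partition; such degenerate
    # candidates are dropped — for a constant gene this empties P entirely
    # and triggers the mean fallback
    return mids[mids < e[-1]]


def partition_entropy(expr, labels, t: float) -> float:
    """Weighted conditional class entropy of the partition at threshold t.

    In [0, 1] for two classes; 0 iff both sides are pure.  An empty side
    contributes nothing.
    """
    expr = np.asarray(expr, dtype=float)
    lab = np.array([str(v) for v in labels])
    classes = sorted(set(lab))
    low = expr <= t
    n = expr.size
    total = 0.0
    for side in (low, ~low):
        ns = int(side.sum())
        if ns == 0:
            continue
        h = 0.0
        for cls in classes:
            k = int(np.sum(side & (lab == cls)))
            if 0 < k < ns:
                frac = k / ns
                h -= frac * math.log2(frac)
        total += (ns / n) * h
    return total


def rule_direction(expr, labels, t: float,
                   classes: tuple[str, str] | None = None) -> str:
    """Orientation of the threshold rule.

    ``leq_is_c1`` when the default rule (<= t -> c1) classifies strictly
    more training samples correctly than incorrectly; the exact tie
    reverses, per the stated inequality (correct <= incorrect -> reverse).
    """
    lab = np.array([str(v) for v in labels])
    if classes is None:
        uniq = sorted(set(lab))
        classes = (uniq[0], uniq[1])
    part = partition_at(np.asarray(expr, dtype=float), lab, t, classes)
    correct = part.p11 + part.p22
    incorrect = part.p12 + part.p21
    return LEQ_IS_C1 if correct > incorrect else LEQ_IS_C2


def optimal_cut_point(expr, labels,
                      classes: tuple[str, str] | None = None) -> CutPointResult:
    """Entropy-minimizing cut point with direction, for one gene.

    Entropy ties among candidates resolve to the smallest threshold.  An
    empty candidate set falls back to the mean expression
    (``fallback_used=True``).
    """
    expr = np.asarray(expr, dtype=float)
    cands = candidate_cut_points(expr, labels)
    if cands.size == 0:
        t_opt = float(expr.mean())
        ent = partition_entropy(expr, labels, t_opt)
        return CutPointResult(t_opt, ent, rule_direction(expr, labels, t_opt,
                                                         classes), 0, True)
    best_t, best_e = None, math.inf
    for t in cands:  # ascending, so strict < keeps the smallest tied t
        e = partition_entropy(expr, labels, float(t))
        if e < best_e:
            best_t, best_e = float(t), e
    return CutPointResult(best_t, best_e,
                          rule_direction(expr, labels, best_t, classes),
                          int(cands.size), False)
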