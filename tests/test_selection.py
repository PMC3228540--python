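"""Gene scoring and selection, checked against independent oracles.

The t-test oracle reimplements the pooled two-sample t formula and the
t CDF through a continued-fraction regularized incomplete beta, with no
scipy involvement.  The WMW oracle enumerates every assignment of ranks to
the first group.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from onegene import (NoInformativeGeneError, SimulationConfig, generate,
                     score_all_genes, select_top_gene, significant_genes,
                     t_score, wmw_score)
from onegene.selection import _wmw_normal_approx

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracles

def _betacf(a, b, x, tol=1e-15, max_iter=300):
    """Continued fraction for the incomplete beta (Lentz's method)."""
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, max_iter):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < tol:
            return h
    raise RuntimeError("betacf did not converge")


def _reg_inc_beta(a, b, x):
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
                + a * math.log(x) + b * math.log(1.0 - x))
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def pooled_t_oracle(x1, x2):
    """Two-sided pooled-variance t-test from first principles."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    t = (x1.mean() - x2.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    x = df / (df + t * t)
    p = _reg_inc_beta(df / 2.0, 0.5, x)
    return t, p


def wmw_exact_oracle(x1, x2):
    """Two-sided exact WMW p by enumerating all rank assignments."""
    pooled = np.concatenate([x1, x2])
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x1)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(sorted(ranks)[i] for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(1.0, p)


# ---------------------------------------------------------------------------
# t-test

class TestTScore:
    def test_agrees_with_first_principles_oracle(self):
        x1 = (1.1, 2.0, 2.9)
        x2 = (4.8, 6.1, 7.0)
        stat, p, degen = t_score(x1, x2)
        t_ref, p_ref = pooled_t_oracle(x1, x2)
        assert not degen
        assert stat == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_oracle_agreement_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1, n2 = rng.integers(2, 15, size=2)
            x1 = rng.normal(size=n1)
            x2 = rng.normal(rng.normal(), 1 + rng.random(), size=n2)
            stat, p, _ = t_score(x1, x2)
            t_ref, p_ref = pooled_t_oracle(x1, x2)
            assert stat == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_give_zero_statistic(self):
        stat, p, _ = t_score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_constant_groups_equal_means_degenerate(self):
        stat, p, degen = t_score([2.0, 2.0], [2.0, 2.0])
        assert (stat, p, degen) == (0.0, 1.0, True)

    def test_constant_groups_different_means_perfect_separation(self):
        stat, p, degen = t_score([1.0, 1.0, 1.0], [11.0, 11.0, 11.0])
        assert p == 0.0 and degen
        assert stat == -math.inf  # sign follows mean difference

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(size=6), rng.normal(1.0, size=8)
        s0, p0, _ = t_score(x1, x2)
        s1, p1, _ = t_score(x1 + 100.0, x2 + 100.0)
        s2, p2, _ = t_score(3.0 * x1, 3.0 * x2)
        assert s1 == pytest.approx(s0) and p1 == pytest.approx(p0)
        assert s2 == pytest.approx(s0) and p2 == pytest.approx(p0)

    def test_welch_option_differs_under_unequal_variance(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(0, 1, size=10)
        x2 = rng.normal(1, 5, size=4)
        _, p_pooled, _ = t_score(x1, x2, equal_var=True)
        _, p_welch, _ = t_score(x1, x2, equal_var=False)
        assert p_pooled != p_welch


# ---------------------------------------------------------------------------
# WMW

class TestWmwScore:
    def test_complete_separation_exact_p(self):
        """n1 = n2 = 3, complete separation: p = 2/C(6,3) = 0.1."""
        _, p, _ = wmw_score([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)
        _, p_ref = None, wmw_exact_oracle(np.array([1., 2., 3.]),
                                          np.array([4., 5., 6.]))
        assert p == pytest.approx(p_ref)

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            x1 = rng.normal(size=n1)
            x2 = rng.normal(0.5, size=n2)
            _, p, _ = wmw_score(x1, x2)
            assert p == pytest.approx(wmw_exact_oracle(x1, x2), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p, _ = wmw_score([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_all_identical_degenerate(self):
        _, p, degen = wmw_score([5.0, 5.0], [5.0, 5.0])
        assert p == 1.0 and degen

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x1, x2 = rng.normal(size=12), rng.normal(0.7, size=14)
        s0, p0, _ = wmw_score(x1, x2)
        s1, p1, _ = wmw_score(x1 ** 3, x2 ** 3)
        assert s1 == s0 and p1 == p0

    def test_approx_branch_matches_scipy(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            x1 = rng.normal(size=15)
            x2 = rng.normal(0.5, size=18)
            _, p, _ = wmw_score(x1, x2)
            ref = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=True).pvalue
            assert p == pytest.approx(float(ref), abs=1e-12)

    def test_approx_with_ties_matches_scipy(self):
        rng = np.random.default_rng(31)
        x1 = rng.integers(0, 5, size=14).astype(float)
        x2 = rng.integers(1, 6, size=12).astype(float)
        _, p, _ = wmw_score(x1, x2)
        ref = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                                 method="asymptotic",
                                 use_continuity=True).pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_exact_vs_approx_sanity_band(self):
        """n1 = n2 = 10, no ties: the two branches agree within 0.01."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            x1, x2 = rng.normal(size=10), rng.normal(0.8, size=10)
            _, p_exact, _ = wmw_score(x1, x2, exact_max_n=20)
            _, p_approx, _ = wmw_score(x1, x2, exact_max_n=0)
            assert abs(p_exact - p_approx) < 0.01


# ---------------------------------------------------------------------------
# ranking and selection

class TestScoreAllGenes:
    @pytest.mark.parametrize("method", ["t", "wmw"])
    def test_planted_gene_ranks_first(self, method):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(10, 24))
        values[5, 12:] += 4.0  # only gene 5 shifts with class
        ds = make_dataset(values, ["A"] * 12 + ["B"] * 12)
        scores = score_all_genes(ds, method)
        assert scores[0].order_number == 5
        assert select_top_gene(ds, method).gene_id == "g5"

    @pytest.mark.parametrize("method", ["t", "wmw"])
    def test_duplicate_gene_tie_breaks_to_smaller_order(self, method):
        rng = np.random.default_rng(18)
        row = rng.normal(size=12)
        row[6:] += 3.0
        noise = rng.normal(size=12)
        ds = make_dataset([noise, row, row], ["A"] * 6 + ["B"] * 6)
        scores = score_all_genes(ds, method)
        assert scores[0].p_value == scores[1].p_value
        assert scores[0].order_number == 1
        assert select_top_gene(ds, method).order_number == 1

    @pytest.mark.parametrize("method", ["t", "wmw"])
    def test_sample_permutation_leaves_ranking_unchanged(self, method):
        rng = np.random.default_rng(19)
        values = rng.normal(size=(8, 14))
        values[2, 7:] += 2.0
        labels = ["A"] * 7 + ["B"] * 7
        ds = make_dataset(values, labels)
        perm = rng.permutation(14)
        ds_perm = make_dataset(values[:, perm], [labels[i] for i in perm])
        r1 = [(s.order_number, s.p_value) for s in score_all_genes(ds, method)]
        r2 = [(s.order_number, s.p_value)
              for s in score_all_genes(ds_perm, method)]
        assert [o for o, _ in r1] == [o for o, _ in r2]
        for (_, p1), (_, p2) in zip(r1, r2):
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_deterministic_repeat(self, planted_dataset):
        ds, _ = planted_dataset
        a = score_all_genes(ds, "t")
        b = score_all_genes(ds, "t")
        assert a == b

    def test_all_degenerate_raises(self):
        ds = make_dataset(np.ones((3, 6)), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(NoInformativeGeneError):
            select_top_gene(ds, "t")


class TestSignificantGenes:
    def test_null_count_is_small(self):
        """1000 pure-noise genes at alpha = 0.001: expected count ~ 1."""
        counts = []
        for seed in range(5):
            ds, _ = generate(SimulationConfig(
                n1=15, n2=15, n_genes=1000, n_informative=0,
                effect_sizes=(), seed=seed))
            counts.append(len(significant_genes(ds, 0.001)))
        assert all(c <= 10 for c in counts)

    def test_alpha_one_returns_all_testable_genes(self, tiny_dataset):
        assert len(significant_genes(tiny_dataset, 1.0)) == 3

    def test_huge_effect_gene_present(self, planted_dataset):
        ds, truth = planted_dataset
        hits = {s.order_number for s in significant_genes(ds, 0.001)}
        assert truth.informative_genes[0] in hits

    def test_strict_inequality(self):
        rng = np.random.default_rng(44)
        values = rng.normal(size=(20, 12))
        ds = make_dataset(values, ["A"] * 6 + ["B"] * 6)
        scores = score_all_genes(ds, "t")
        alpha = scores[3].p_value  # use an attained p as the level
        sig = significant_genes(ds, alpha)
        assert all(s.p_value < alpha for s in sig)
        assert scores[3].order_number not in {s.order_number for s in sig}
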