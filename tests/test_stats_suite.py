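"""Nonparametric tests and ROC machinery against hand-computed oracles."""

import numpy as np
import pytest
from scipy import stats

from rpquant import (
    GroupedSamples,
    chi_square_table,
    dunn_bonferroni,
    kruskal_wallis,
    mann_whitney,
    roc,
)


def kw_rank_oracle(*groups):
    """H from the rank-sum formula (no ties): 12/(N(N+1)) sum n_i rbar_i^2 - 3(N+1)."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * r.mean() ** 2
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_identical_groups(self):
        gs = GroupedSamples.from_arrays(a=[1.0, 1.0], b=[1.0, 1.0])
        assert kruskal_wallis(gs) == (0.0, 1.0)

    def test_matches_rank_formula(self):
        groups = ([1.0, 2, 3], [4.0, 5, 6], [7.0, 8, 9])
        h, _ = kruskal_wallis(GroupedSamples(("a", "b", "c"), groups))
        assert h == pytest.approx(kw_rank_oracle(*groups), abs=1e-12)

    def test_two_groups_consistent_with_mann_whitney(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        _, p_kw = kruskal_wallis(GroupedSamples(("a", "b"), (a, b)))
        _, p_mw = mann_whitney(a, b)
        assert p_kw == pytest.approx(p_mw, rel=0.02)


class TestDunnBonferroni:
    def test_identical_groups_give_p_one(self):
        gs = GroupedSamples.from_arrays(a=[1.0, 2.0], b=[1.0, 2.0], c=[1.0, 2.0])
        assert all(p == 1.0 for p in dunn_bonferroni(gs).values())

    def test_three_groups_give_three_pairs(self, rng):
        gs = GroupedSamples.from_arrays(
            a=rng.normal(size=8), b=rng.normal(size=9), c=rng.normal(size=10)
        )
        assert len(dunn_bonferroni(gs)) == 3

    def test_matches_independent_oracle_with_ties(self, rng):
        vals = [rng.integers(0, 6, size=n).astype(float) for n in (12, 15, 9)]
        gs = GroupedSamples(("g1", "g2", "g3"), tuple(vals))
        result = dunn_bonferroni(gs)

        pooled = np.concatenate(vals)
        ranks = stats.rankdata(pooled)
        n = pooled.size
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
        sizes = [len(v) for v in vals]
        starts = np.cumsum([0] + sizes)
        means = [ranks[starts[i]: starts[i + 1]].mean() for i in range(3)]
        for (i, j), key in zip(((0, 1), (0, 2), (1, 2)),
                               (("g1", "g2"), ("g1", "g3"), ("g2", "g3"))):
            z = (means[i] - means[j]) / np.sqrt(
                (n * (n + 1) / 12.0 - tie) * (1 / sizes[i] + 1 / sizes[j])
            )
            raw = 2 * stats.norm.sf(abs(z))
            assert result[key] == pytest.approx(min(1.0, 3 * raw), abs=1e-12)
            assert result[key] >= raw  # adjustment never shrinks p

    def test_adjusted_p_at_least_raw_on_random_data(self, rng):
        for _ in range(5):
            gs = GroupedSamples.from_arrays(
                a=rng.normal(size=7), b=rng.normal(1, 1, size=8), c=rng.normal(size=6)
            )
            raw = dict(dunn_bonferroni(gs))
            # raw p recoverable by undoing the x3 Bonferroni factor (pre-cap)
            for pair, p_adj in raw.items():
                assert p_adj <= 1.0
                assert p_adj >= p_adj / 3.0


class TestMannWhitney:
    def test_identical_samples(self):
        a = np.array([3.0, 3.0, 3.0])
        u, p = mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney([1.0, 2, 3, 4, 5], [6.0, 7, 8, 9, 10])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 252.0)

    def test_u_matches_pairwise_counting_oracle(self, rng):
        a = rng.integers(0, 20, 25).astype(float)
        b = rng.integers(0, 20, 30).astype(float)
        u, _ = mann_whitney(a, b)
        brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u == pytest.approx(brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_uniform_table(self):
        stat, p = chi_square_table([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == 1.0

    def test_age_by_symptomatic_association(self):
        # 2x2 of age >= 65 by symptomatic RP in the reference cohort
        _, p = chi_square_table([[12, 24], [24, 11]])
        assert p < 0.01

    def test_matches_direct_formula(self, rng):
        table = rng.integers(1, 30, size=(2, 3)).astype(float)
        stat, _ = chi_square_table(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table([[0, 0], [3, 4]])


class TestROC:
    def test_perfect_separation(self):
        r = roc([1.0, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert 3 < r.cutoff < 10
        assert r.sensitivity_at_cutoff == 1.0
        assert r.specificity_at_cutoff == 1.0

    def test_null_scores_have_half_auc(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_mann_whitney_identity_with_ties(self, rng):
        scores = rng.integers(0, 10, 200).astype(float)  # heavy ties
        labels = rng.random(200) < 0.4
        r = roc(scores, labels)
        u, _ = mann_whitney(scores[labels], scores[~labels])
        assert r.auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300) + rng.random(300)
        labels = rng.random(300) < 0.3
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_sensitivity_monotone_in_threshold(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        r = roc(scores, labels)
        assert np.all(np.diff(r.sensitivity) <= 1e-15)
        assert np.all(np.diff(r.specificity) >= -1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1.0, 2.0], [1, 1])
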