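"""Nonparametric group comparisons and ROC cut-off machinery.

Wraps the scipy implementations of the classical tests (Kruskal-Wallis,
Mann-Whitney, Pearson chi-square) and adds the two pieces scipy does not
ship: Dunn's post-hoc z-tests with Bonferroni adjustment, and an ROC with a
Youden-index cut-off, the rule used to dichotomise RPv max (symptomatic
vs non-symptomatic pneumonitis) and mean lung dose.

All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupedSamples",
    "ROCResult",
    "kruskal_wallis",
    "dunn_bonferroni",
    "mann_whitney",
    "chi_square_table",
    "roc",
    "median_iqr",
]


@dataclass(frozen=True)
class GroupedSamples:
    """Labelled continuous samples, e.g. RPv max by RP grade max."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("one label per group required")
        if len(self.labels) < 2:
            raise ValueError("at least two groups required")
        object.__setattr__(
            self, "values", tuple(np.asarray(v, dtype=float) for v in self.values)
        )
        if any(v.size == 0 for v in self.values):
            raise ValueError("all groups must be non-empty")

    @classmethod
    def from_arrays(cls, **groups) -> "GroupedSamples":
        return cls(tuple(groups.keys()), tuple(np.asarray(v) for v in groups.values()))


def kruskal_wallis(groups: GroupedSamples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    vals = groups.values
    if sum(v.size for v in vals) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(np.concatenate(vals)) == 0:
        # all observations identical: H = 0 by convention, p = 1
        return 0.0, 1.0
    h, p = stats.kruskal(*vals)
    return float(h), float(p)


def dunn_bonferroni(groups: GroupedSamples) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled ranks, Bonferroni-adjusted.

    The z statistic for groups i, j compares mean pooled ranks with the
    tie-corrected null variance; each two-sided p is multiplied by the
    number of pairs and capped at 1.
    """
    vals = groups.values
    pooled = np.concatenate(vals)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))

    sizes = [v.size for v in vals]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(vals))]

    k = len(vals)
    n_pairs = k * (k - 1) // 2
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            out[(groups.labels[i], groups.labels[j])] = min(1.0, p * n_pairs)
    return out


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact p when the smaller sample has <= 8 observations and there are no
    ties; otherwise the tie-corrected normal approximation (no continuity
    correction, so identical samples give p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        # every observation tied: U at its null mean, no evidence either way
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_table(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on an r x k contingency table.

    ``correction=True`` applies the Yates continuity correction (2x2 only),
    matching common statistical-package defaults; the uncorrected statistic
    is the default here.
    """
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every margin must be positive")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ROCResult:
    """ROC of a continuous score against a binary outcome.

    Thresholds are midpoints between consecutive distinct scores (plus one
    below the minimum and one above the maximum); a case is called positive
    when its score is >= the threshold. ``cutoff`` maximises the Youden
    index J = sensitivity + specificity - 1, ties resolved to the lower
    threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    youden_at_cutoff: float


def roc(scores, labels) -> ROCResult:
    """ROC analysis with Youden-optimal cut-off; higher score = more positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    distinct = np.unique(scores)
    span = distinct[-1] - distinct[0] if distinct.size > 1 else 1.0
    thresholds = np.concatenate(
        [[distinct[0] - 0.5 * span - 0.5], (distinct[:-1] + distinct[1:]) / 2.0,
         [distinct[-1] + 0.5 * span + 0.5]]
    )

    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg, thresholds, side="left") / n_neg

    # AUC via the tie-corrected rank (Mann-Whitney) identity
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        cutoff=float(thresholds[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
        youden_at_cutoff=float(youden[best]),
    )


def median_iqr(values) -> tuple[float, float, float]:
    """Median and IQR bounds (25th/75th percentile, linear interpolation)."""
    v = np.asarray(values, dtype=float)
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )
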