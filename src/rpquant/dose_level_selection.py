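"""Selection of the isodose level that delineates radiation-induced lesions.

Two per-level gates are scanned over the integer dose levels 1..66 Gy:

(a) the lung Vd (% of lung receiving >= d Gy) must be significantly rank-
    correlated (Spearman, two-sided) with RPv max across the cohort, and
(b) the d-Gy isodose region must cover at least ``lesion_threshold`` (80%)
    of the lesion volume in strictly more than ``patient_fraction_threshold``
    (80%) of patients, separately within grade-1 and grade-2 patients.

Because low levels trivially cover everything, the *highest* level passing
both gates is selected; on the study cohort this procedure yields 26 Gy.
Grade-3 patients are excluded from the coverage gate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "SelectionResult",
    "spearman",
    "correlation_sweep",
    "coverage_pass_fraction",
    "select_dose_level",
]


@dataclass(frozen=True)
class CohortTable:
    """Per-patient derived metrics feeding selection, ROC and group stats.

    ``vx_matrix`` and ``coverage_matrix`` are (n_patients, n_levels) arrays
    over ``levels_gy``; Vx in percent, coverage as a fraction. ``rpv_max``
    is in percent to match reporting conventions.
    """

    rpv_max: np.ndarray
    grade_max: np.ndarray
    levels_gy: np.ndarray = field(default_factory=lambda: np.arange(1, 67))
    vx_matrix: np.ndarray | None = None
    coverage_matrix: np.ndarray | None = None
    mean_lung_dose_gy: np.ndarray | None = None
    age: np.ndarray | None = None
    symptomatic: np.ndarray | None = None
    treatment_group: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.rpv_max)
        for name in ("grade_max", "vx_matrix", "coverage_matrix",
                     "mean_lung_dose_gy", "age", "symptomatic", "treatment_group"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} rows, expected {n}")

    @property
    def n_patients(self) -> int:
        return len(self.rpv_max)

    def level_index(self, level: float) -> int:
        idx = np.nonzero(np.asarray(self.levels_gy) == level)[0]
        if idx.size == 0:
            raise KeyError(f"level {level} Gy not in cohort table")
        return int(idx[0])


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the dose-level scan, with a full per-level audit trail.

    ``audit`` has one row per candidate level: rho, p, the per-grade
    coverage pass fractions, and the reason a level was rejected (empty for
    the passing levels). ``selected_level_gy`` is None when no level passes
    both gates.
    """

    selected_level_gy: int | None
    audit: pd.DataFrame


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided p by full enumeration of rank permutations (small n)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    c = base - base.mean()
    denom = np.sqrt((c**2).sum() * ((perms - base.mean()) ** 2).sum(axis=1))
    rhos = (perms - base.mean()) @ c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p; average ranks on ties.

    p uses full permutation enumeration for n <= 8 (ties excepted) and the
    t-distribution approximation otherwise. Constant inputs give (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= 8 and no_ties:
        p = _spearman_exact_p(float(rho), n)
    return float(rho), float(p)


def correlation_sweep(cohort: CohortTable) -> pd.DataFrame:
    """Spearman rho/p of RPv max against Vd for every candidate level d."""
    if cohort.vx_matrix is None:
        raise ValueError("cohort table has no Vx matrix")
    if cohort.n_patients < 5:
        raise ValueError("need at least 5 patients for the correlation sweep")
    rows = []
    for i, level in enumerate(np.asarray(cohort.levels_gy)):
        rho, p = spearman(cohort.vx_matrix[:, i], cohort.rpv_max)
        rows.append({"level_gy": int(level), "rho": rho, "p": p})
    return pd.DataFrame(rows)


def coverage_pass_fraction(
    cohort: CohortTable,
    level: float,
    lesion_threshold: float = 0.80,
    grades: tuple[int, ...] = (1, 2),
) -> float:
    """Fraction of grade-filtered patients whose lesion coverage at
    ``level`` is >= ``lesion_threshold`` (inclusive)."""
    if cohort.coverage_matrix is None:
        raise ValueError("cohort table has no coverage matrix")
    sel = np.isin(cohort.grade_max, grades)
    if not sel.any():
        raise ValueError(f"no patients with grade in {grades}")
    cov = cohort.coverage_matrix[sel, cohort.level_index(level)]
    return float(np.mean(cov >= lesion_threshold))


def select_dose_level(
    cohort: CohortTable,
    alpha: float = 0.05,
    lesion_threshold: float = 0.80,
    patient_fraction_threshold: float = 0.80,
    coverage_grades: tuple[int, ...] = (1, 2),
) -> SelectionResult:
    """Scan levels 1..66 Gy and return the highest level passing both gates.

    Gate (a): Spearman p < ``alpha`` for Vd vs RPv max. Gate (b): the
    lesion-coverage criterion (>= ``lesion_threshold`` of the lesion inside
    the isodose region) holds in strictly more than
    ``patient_fraction_threshold`` of patients within each grade in
    ``coverage_grades`` separately. Returns ``selected_level_gy=None`` with
    the audit trail when no level passes.
    """
    sweep = correlation_sweep(cohort)
    rows = []
    passing: list[int] = []
    for _, r in sweep.iterrows():
        level = int(r["level_gy"])
        entry = {"level_gy": level, "rho": r["rho"], "p": r["p"]}
        reasons = []
        if not (np.isfinite(r["p"]) and r["p"] < alpha):
            reasons.append(f"correlation not significant (p={r['p']:.3g})")
        for g in coverage_grades:
            frac = coverage_pass_fraction(
                cohort, level, lesion_threshold=lesion_threshold, grades=(g,)
            )
            entry[f"pass_fraction_grade{g}"] = frac
            if not frac > patient_fraction_threshold:
                reasons.append(
                    f"grade-{g} coverage pass fraction {frac:.1%} "
                    f"not > {patient_fraction_threshold:.0%}"
                )
        entry["passes"] = not reasons
        entry["rejection"] = "; ".join(reasons)
        rows.append(entry)
        if not reasons:
            passing.append(level)
    audit = pd.DataFrame(rows)
    return SelectionResult(
        selected_level_gy=max(passing) if passing else None,
        audit=audit,
    )
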