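"""Cohort-level report builders: the table-shaped outputs of the pipeline.

Builders take a :class:`~rpquant.dose_level_selection.CohortTable` and emit
tidy or wide pandas frames ready for CSV export: dose-metric medians/IQRs
grouped by RP grade (with Kruskal-Wallis and Dunn-Bonferroni columns), the
symptomatic/non-symptomatic split (Mann-Whitney), the age-stratified split,
and the ROC summary for predicting symptomatic pneumonitis. Percentages are
reported to one decimal; internal computation keeps full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose_level_selection import CohortTable
from .stats_suite import (
    GroupedSamples,
    dunn_bonferroni,
    kruskal_wallis,
    mann_whitney,
    median_iqr,
    roc,
)

__all__ = [
    "cohort_metrics_frame",
    "coverage_frame",
    "cohort_table_from_frames",
    "grade_group_table",
    "symptomatic_table",
    "age_stratified_table",
    "roc_report",
]


def _metric_rows(cohort: CohortTable):
    """(label, values) pairs for MLD, RPv max, and every Vx level."""
    yield "mean_lung_dose_gy", cohort.mean_lung_dose_gy
    yield "rpv_max_pct", cohort.rpv_max
    for i, level in enumerate(np.asarray(cohort.levels_gy)):
        yield f"v{int(level)}_pct", cohort.vx_matrix[:, i]


def cohort_metrics_frame(cohort: CohortTable) -> pd.DataFrame:
    """Wide per-patient frame: grade, symptoms, MLD, RPv max, V1..V66."""
    data = {
        "patient_id": [f"P{i:04d}" for i in range(1, cohort.n_patients + 1)],
        "grade_max": cohort.grade_max,
        "rpv_max_pct": cohort.rpv_max,
    }
    if cohort.symptomatic is not None:
        data["symptomatic"] = cohort.symptomatic.astype(int)
    if cohort.age is not None:
        data["age"] = cohort.age
    if cohort.treatment_group is not None:
        data["treatment_group"] = cohort.treatment_group
    if cohort.mean_lung_dose_gy is not None:
        data["mean_lung_dose_gy"] = cohort.mean_lung_dose_gy
    if cohort.vx_matrix is not None:
        for i, level in enumerate(np.asarray(cohort.levels_gy)):
            data[f"v{int(level)}_pct"] = cohort.vx_matrix[:, i]
    return pd.DataFrame(data)


def coverage_frame(cohort: CohortTable) -> pd.DataFrame:
    """Tidy lesion-coverage frame: (patient_id, level_gy, coverage_fraction)."""
    if cohort.coverage_matrix is None:
        raise ValueError("cohort table has no coverage matrix")
    rows = []
    for i in range(cohort.n_patients):
        for j, level in enumerate(np.asarray(cohort.levels_gy)):
            rows.append(
                {
                    "patient_id": f"P{i + 1:04d}",
                    "level_gy": int(level),
                    "coverage_fraction": cohort.coverage_matrix[i, j],
                }
            )
    return pd.DataFrame(rows)


def cohort_table_from_frames(
    metrics: pd.DataFrame, coverage: pd.DataFrame | None = None
) -> CohortTable:
    """Rebuild a cohort table from the CSV frames written by the CLI."""
    metrics = metrics.sort_values("patient_id").reset_index(drop=True)
    levels = sorted(
        int(c[1:-4]) for c in metrics.columns if c.startswith("v") and c.endswith("_pct")
    )
    vx = (
        metrics[[f"v{d}_pct" for d in levels]].to_numpy(dtype=float) if levels else None
    )
    cov = None
    if coverage is not None:
        pivot = coverage.pivot(
            index="patient_id", columns="level_gy", values="coverage_fraction"
        ).sort_index()
        if levels and list(pivot.columns) != levels:
            pivot = pivot.reindex(columns=levels)
        cov = pivot.to_numpy(dtype=float)
        levels = list(pivot.columns) if not levels else levels
    return CohortTable(
        rpv_max=metrics["rpv_max_pct"].to_numpy(dtype=float),
        grade_max=metrics["grade_max"].to_numpy(dtype=int),
        levels_gy=np.asarray(levels if levels else range(1, 67)),
        vx_matrix=vx,
        coverage_matrix=cov,
        mean_lung_dose_gy=(
            metrics["mean_lung_dose_gy"].to_numpy(dtype=float)
            if "mean_lung_dose_gy" in metrics
            else None
        ),
        age=metrics["age"].to_numpy(dtype=float) if "age" in metrics else None,
        symptomatic=(
            metrics["symptomatic"].to_numpy(dtype=bool)
            if "symptomatic" in metrics
            else None
        ),
        treatment_group=(
            metrics["treatment_group"].to_numpy()
            if "treatment_group" in metrics
            else None
        ),
    )


def _fmt_groups(values_by_group: dict[str, np.ndarray]) -> dict[str, float]:
    out = {}
    for label, vals in values_by_group.items():
        med, q1, q3 = median_iqr(vals)
        out[f"{label}_median"] = round(med, 1)
        out[f"{label}_iqr_low"] = round(q1, 1)
        out[f"{label}_iqr_high"] = round(q3, 1)
    return out


def grade_group_table(cohort: CohortTable) -> pd.DataFrame:
    """Dose metrics by RP grade max: medians, IQRs, KW p, Dunn pairwise p."""
    grades = sorted(set(int(g) for g in cohort.grade_max))
    rows = []
    for label, values in _metric_rows(cohort):
        by_grade = {
            f"grade{g}": np.asarray(values)[cohort.grade_max == g] for g in grades
        }
        row: dict = {"metric": label, **_fmt_groups(by_grade)}
        if len(grades) >= 2:
            gs = GroupedSamples(tuple(by_grade.keys()), tuple(by_grade.values()))
            _, row["kw_p"] = kruskal_wallis(gs)
            if len(grades) > 2:
                for (a, b), p in dunn_bonferroni(gs).items():
                    row[f"dunn_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def symptomatic_table(cohort: CohortTable) -> pd.DataFrame:
    """Dose metrics split by symptomatic status, with Mann-Whitney p."""
    if cohort.symptomatic is None:
        raise ValueError("cohort table has no symptomatic flags")
    rows = []
    for label, values in _metric_rows(cohort):
        v = np.asarray(values)
        no, yes = v[~cohort.symptomatic], v[cohort.symptomatic]
        row = {"metric": label, **_fmt_groups({"no_symptoms": no, "symptomatic": yes})}
        _, row["mw_p"] = mann_whitney(no, yes)
        rows.append(row)
    return pd.DataFrame(rows)


def age_stratified_table(cohort: CohortTable, age_cut: float = 65.0) -> pd.DataFrame:
    """Symptomatic split within age strata (< cut / >= cut)."""
    if cohort.age is None or cohort.symptomatic is None:
        raise ValueError("cohort table needs age and symptomatic columns")
    rows = []
    for stratum, sel in (
        (f"age<{age_cut:g}", cohort.age < age_cut),
        (f"age>={age_cut:g}", cohort.age >= age_cut),
    ):
        sympt = cohort.symptomatic[sel]
        if sympt.all() or not sympt.any():
            continue  # split undefined within this stratum
        for label, values in _metric_rows(cohort):
            v = np.asarray(values)[sel]
            row = {
                "stratum": stratum,
                "metric": label,
                **_fmt_groups({"no_symptoms": v[~sympt], "symptomatic": v[sympt]}),
            }
            _, row["mw_p"] = mann_whitney(v[~sympt], v[sympt])
            rows.append(row)
    return pd.DataFrame(rows)


def roc_report(cohort: CohortTable) -> dict:
    """ROC summaries (AUC, Youden cut-off, sens/spec) for RPv max and MLD."""
    if cohort.symptomatic is None:
        raise ValueError("cohort table has no symptomatic flags")
    out = {"cutoff_rule": "Youden index (max sensitivity + specificity - 1)"}
    scores = {"rpv_max_pct": cohort.rpv_max}
    if cohort.mean_lung_dose_gy is not None:
        scores["mean_lung_dose_gy"] = cohort.mean_lung_dose_gy
    for name, score in scores.items():
        r = roc(score, cohort.symptomatic)
        out[name] = {
            "auc": round(r.auc, 3),
            "cutoff": round(r.cutoff, 2),
            "sensitivity": round(r.sensitivity_at_cutoff, 2),
            "specificity": round(r.specificity_at_cutoff, 2),
        }
    return out
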