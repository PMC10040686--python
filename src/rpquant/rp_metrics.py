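"""Per-patient longitudinal pneumonitis bookkeeping.

Each patient has up to three follow-up CT scans after radiotherapy, each
scored with a CTCAE grade (0-3) and an RPv (lesion volume / total lung
volume). This module derives the per-patient summary used everywhere
downstream: the maximum grade, the RPv max attained at that grade, the
interval in days from radiotherapy completion to its onset, and the
symptomatic flag (grade >= 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

__all__ = [
    "MORPHOLOGY_PATTERNS",
    "RPAssessment",
    "DerivedRP",
    "PatientRecord",
    "derive_rp",
    "interval_range",
    "grade_distribution",
]

#: Four CT-appearance patterns of pneumonitis (consolidation / ground-glass).
MORPHOLOGY_PATTERNS = (
    "diffuse consolidation",
    "diffuse GGO",
    "patchy consolidation+GGO",
    "patchy GGO",
)


@dataclass(frozen=True)
class RPAssessment:
    """One follow-up scan: day since RT completion, CTCAE grade, RPv."""

    scan_index: int
    day: int
    grade: int
    rpv: float
    morphology: str | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if self.grade not in (0, 1, 2, 3):
            raise ValueError(f"grade must be in 0..3, got {self.grade}")
        if not 0.0 <= self.rpv <= 1.0:
            raise ValueError(f"rpv must be a fraction in [0, 1], got {self.rpv}")
        if self.morphology is not None and self.morphology not in MORPHOLOGY_PATTERNS:
            raise ValueError(f"unknown morphology {self.morphology!r}")


@dataclass(frozen=True)
class DerivedRP:
    """Per-patient summary derived from the scan series."""

    rp_grade_max: int
    rpv_max: float
    interval_to_grade_max: int
    symptomatic: bool


@dataclass
class PatientRecord:
    """Clinical covariates plus the scan series and survival endpoints.

    ``survival`` maps endpoint name (``LRPFS``/``PFS``/``OS``) to
    ``(time_days, event)``.
    """

    patient_id: str
    age: float
    sex: str
    rt_dose_gy: float
    technique: str = "IMRT"
    combined_treatment: str = "none"
    purpose: str = "curative"
    treatment_site: str = "lung"
    ptv_h_volume_cc: float | None = None
    assessments: list[RPAssessment] = field(default_factory=list)
    survival: dict[str, tuple[float, bool]] = field(default_factory=dict)

    @property
    def derived(self) -> DerivedRP:
        return derive_rp(self.assessments)


def _check_series(assessments: Sequence[RPAssessment]) -> None:
    if not assessments:
        raise ValueError("at least one assessment is required")
    days = [a.day for a in assessments]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError(f"scan days must be strictly increasing, got {days}")


def derive_rp(assessments: Sequence[RPAssessment]) -> DerivedRP:
    """Summarise a chronological scan series.

    The maximum grade over the series defines the patient's RP grade max.
    Among the scans attaining that grade, the representative scan is the one
    with the largest RPv (earliest day on ties), and its day is the interval
    to RP grade max; RPv max is that largest RPv. Symptomatic means grade
    max >= 2.
    """
    _check_series(assessments)
    grade_max = max(a.grade for a in assessments)
    at_max = [a for a in assessments if a.grade == grade_max]
    representative = max(at_max, key=lambda a: (a.rpv, -a.day))
    return DerivedRP(
        rp_grade_max=grade_max,
        rpv_max=representative.rpv,
        interval_to_grade_max=representative.day,
        symptomatic=grade_max >= 2,
    )


def interval_range(
    cohort: Iterable[DerivedRP],
    grade_filter: Callable[[int], bool] = lambda g: True,
) -> tuple[int, int]:
    """(min, max) interval to grade max over patients whose grade passes the filter."""
    intervals = [d.interval_to_grade_max for d in cohort if grade_filter(d.rp_grade_max)]
    if not intervals:
        raise ValueError("no patients pass the grade filter")
    return min(intervals), max(intervals)


def grade_distribution(cohort: Sequence[DerivedRP]) -> dict[int, int]:
    """Grade-max distribution as whole percentages of the cohort."""
    if not cohort:
        raise ValueError("cohort is empty")
    counts = Counter(d.rp_grade_max for d in cohort)
    n = len(cohort)
    return {g: round(100.0 * c / n) for g, c in sorted(counts.items())}
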