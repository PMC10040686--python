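"""Synthetic thorax-cohort generator.

Produces phantom patients with the statistical structure the analysis
pipeline assumes: two ellipsoidal lungs on a coarse CT-like grid, a
beam-like dose distribution prescribed 56-66 Gy (sharp target plateau,
Gaussian penumbra, proportional low-dose bath), pneumonitis lesions sown
preferentially where dose exceeds a genesis threshold theta (default
26 Gy), serial follow-up scans with varying lesion extent, CTCAE grades
linked to RPv max through a logistic model with an age effect, and
exponential survival with treatment-group hazard ratios.

The generator is fully deterministic under its seed. Its defaults are
calibrated so that cohort summaries (grade proportions near 51/45/4,
symptomatic fraction near one half, RPv max medians ordered by grade,
first-scan days spanning roughly 5-190) resemble the reference cohort the
pipeline was designed around; the dose-lesion mechanism itself is a
modeling stand-in, not an empirical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .rp_metrics import PatientRecord, RPAssessment, derive_rp
from .volumetrics import (
    DEFAULT_LEVELS_GY,
    VoxelVolume,
    compute_dvh,
    coverage_curve,
    rpv,
    structure_volume_cc,
)
from .dose_level_selection import CohortTable

__all__ = [
    "GeneratorConfig",
    "SyntheticPatient",
    "make_phantom",
    "sow_lesion",
    "assign_outcomes",
    "generate_patient",
    "generate_cohort",
    "cohort_table",
    "sample_outcome_table",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the phantom-cohort model. Units in field names."""

    n_patients: int = 71
    # grid geometry
    grid_shape: tuple[int, int, int] = (36, 36, 24)
    spacing_mm: tuple[float, float, float] = (7.0, 7.0, 8.0)
    # lung anatomy (two ellipsoids, semi-axes in mm)
    lung_semi_axes_mm: tuple[float, float, float] = (42.0, 62.0, 76.0)
    lung_center_offset_mm: float = 56.0
    # beam/dose model
    rx_doses_gy: tuple[float, ...] = (56.0, 60.0, 64.0, 66.0)
    rx_weights: tuple[float, ...] = (1.0, 49.0, 12.0, 9.0)
    target_radius_range_mm: tuple[float, float] = (22.0, 48.0)
    penumbra_sigma_mm: float = 14.0
    bath_sigma_mm: float = 50.0
    bath_fraction: float = 0.30
    # lesion-genesis model: voxelwise probability is
    #   min(s,1) * [base + (1-base) * expit(slope*(d-theta_eff)) *
    #               expit(upper_slope*(theta + width_eff - d))]
    # where severity s > 1 widens the injured band on both sides:
    #   theta_eff = theta - theta_spread*ln(s),  width_eff = width + width_spread*ln(s)
    theta_gy: float = 26.0
    lesion_slope_per_gy: float = 1.5
    lesion_upper_width_gy: float = 10.0
    lesion_upper_slope_per_gy: float = 0.5
    lesion_base_rate: float = 0.004
    severity_median: float = 1.1
    severity_sigma: float = 0.9
    theta_spread_gy: float = 2.5
    width_spread_gy: float = 14.0
    min_component_voxels: int = 3
    morphological_closing: bool = True
    low_dose_lesion_rate: float = 0.03
    # follow-up schedule (days from RT completion)
    first_scan_day_range: tuple[int, int] = (5, 190)
    scan_gap_day_range: tuple[int, int] = (80, 115)
    p_second_scan: float = 55.0 / 71.0
    p_third_scan: float = 43.0 / 55.0
    scan_factor_range: tuple[float, float] = (0.45, 1.0)
    # grade / symptom model
    symptomatic_cutpoint_pct: float = 4.8
    symptomatic_slope_per_pct: float = 2.0
    age_effect_logit: float = 0.8
    age_reference_years: float = 65.0
    grade3_rpv_pct: float = 19.0
    age_range_years: tuple[int, int] = (42, 86)
    # survival model (exponential; hazards per day)
    treatment_groups: tuple[str, ...] = ("none", "target", "chemo", "chemo+IO")
    treatment_weights: tuple[float, ...] = (8.0, 35.0, 25.0, 3.0)
    baseline_hazards_per_day: dict = field(
        default_factory=lambda: {"LRPFS": 1 / 2500.0, "PFS": 1 / 900.0, "OS": 1 / 1600.0}
    )
    lrpfs_hr_chemo: float = 4.68
    os_hr_high_rpv: float = 0.41
    followup_cap_days: float = 730.0

    def validate(self) -> "GeneratorConfig":
        if not 0 < self.theta_gy < max(self.rx_doses_gy):
            raise ValueError("theta must lie inside the achievable dose range")
        for r in (self.lesion_base_rate, self.low_dose_lesion_rate,
                  self.p_second_scan, self.p_third_scan):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rates must be in [0, 1], got {r}")
        return self


@dataclass
class SyntheticPatient:
    """A phantom patient: clinical record, volumes, and latent truth."""

    record: PatientRecord
    dose: VoxelVolume
    lung: VoxelVolume
    lesions: list[VoxelVolume]
    severity: float
    theta_gy: float
    symptomatic_linear_predictor: float
    low_dose_seeded: bool


def _lung_mask(config: GeneratorConfig) -> np.ndarray:
    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.spacing_mm)
    center = (shape - 1) / 2.0 * spacing
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    a, b, c = config.lung_semi_axes_mm
    mask = np.zeros(tuple(shape), dtype=bool)
    for side in (-1.0, 1.0):
        cx = center[0] + side * config.lung_center_offset_mm
        mask |= (
            ((xx - cx) / a) ** 2
            + ((yy - center[1]) / b) ** 2
            + ((zz - center[2]) / c) ** 2
        ) <= 1.0
    return mask


def make_phantom(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[VoxelVolume, VoxelVolume]:
    """Dose grid and lung mask for one phantom patient.

    The target is a sphere centered on a random lung voxel; dose is the
    prescription inside the target, rolled off with a Gaussian penumbra,
    plus a broad proportional low-dose bath, clipped to the prescription.
    """
    config.validate()
    spacing = np.asarray(config.spacing_mm)
    lung = _lung_mask(config)

    rx = float(rng.choice(config.rx_doses_gy,
                          p=np.asarray(config.rx_weights) / np.sum(config.rx_weights)))
    centers = np.argwhere(lung)
    target_center = centers[rng.integers(len(centers))] * spacing
    radius = float(rng.uniform(*config.target_radius_range_mm))

    coords = [np.arange(n) * s for n, s in zip(config.grid_shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    dist2 = (
        (xx - target_center[0]) ** 2
        + (yy - target_center[1]) ** 2
        + (zz - target_center[2]) ** 2
    )
    target = (dist2 <= radius**2).astype(float)
    if not target.any():
        raise ValueError("target sphere lies outside the grid")

    f_pen = ndimage.gaussian_filter(target, sigma=config.penumbra_sigma_mm / spacing)
    f_bath = ndimage.gaussian_filter(target, sigma=config.bath_sigma_mm / spacing)
    if f_pen.max() > 0:
        f_pen = f_pen / f_pen.max()
    if f_bath.max() > 0:
        f_bath = f_bath / f_bath.max()
    dose = rx * np.clip(f_pen + config.bath_fraction * f_bath, 0.0, 1.0)

    return (
        VoxelVolume(dose, tuple(config.spacing_mm)),
        VoxelVolume(lung.astype(np.uint8), tuple(config.spacing_mm)),
    )


def _lesion_probability(
    dose: np.ndarray, config: GeneratorConfig, severity: float = 1.0
) -> np.ndarray:
    """Voxelwise lesion probability for a patient of given severity.

    Logistic rise at the genesis threshold theta combined with a soft upper
    roll-off: injury concentrates in the moderate-dose band just above
    theta rather than filling the whole high-dose target. Severity below 1
    thins the lesion uniformly; severity above 1 widens the injured band on
    both sides of theta, producing the heavy upper tail of RPv seen in
    severe pneumonitis.
    """
    excess = max(0.0, np.log(severity)) if severity > 0 else 0.0
    theta_eff = config.theta_gy - config.theta_spread_gy * excess
    width_eff = config.lesion_upper_width_gy + config.width_spread_gy * excess
    rise = expit(config.lesion_slope_per_gy * (dose - theta_eff))
    fall = expit(
        config.lesion_upper_slope_per_gy * (config.theta_gy + width_eff - dose)
    )
    shape = config.lesion_base_rate + (1.0 - config.lesion_base_rate) * rise * fall
    return min(severity, 1.0) * shape


def sow_lesion(
    dose: VoxelVolume,
    lung: VoxelVolume,
    config: GeneratorConfig,
    rng: np.random.Generator,
    severity: float = 1.0,
    theta_gy: float | None = None,
) -> VoxelVolume:
    """Draw one lesion mask inside the lung, concentrated above theta.

    Voxelwise Bernoulli with the dose-dependent probability, followed by
    morphological closing and removal of components smaller than
    ``min_component_voxels``. ``theta_gy`` overrides the config threshold
    (used for the low-dose-injury outliers).
    """
    if not dose.same_geometry(lung):
        raise ValueError("dose and lung must share geometry")
    cfg = config if theta_gy is None else replace(config, theta_gy=theta_gy)
    lung_arr = lung.mask_array()
    p = np.clip(_lesion_probability(np.asarray(dose.values), cfg, severity), 0.0, 1.0)
    raw = (rng.random(dose.shape) < p) & lung_arr
    if cfg.morphological_closing:
        closed = ndimage.binary_closing(raw, structure=np.ones((3, 3, 3), dtype=bool))
        closed &= lung_arr
    else:
        closed = raw
    labeled, n_comp = ndimage.label(closed)
    if n_comp:
        sizes = ndimage.sum_labels(closed, labeled, index=np.arange(1, n_comp + 1))
        keep = np.flatnonzero(sizes >= cfg.min_component_voxels) + 1
        closed = np.isin(labeled, keep)
    return VoxelVolume(closed.astype(np.uint8), dose.spacing, dose.origin)


def assign_outcomes(
    rpv_max_pct: float,
    age: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    treatment_group: str | None = None,
) -> tuple[int, bool, float, str, dict[str, tuple[float, bool]]]:
    """Grade max, symptomatic flag, linear predictor, group and survival.

    Symptomatic probability is logistic in (RPv max - cutpoint) with an
    additive logit shift for age >= the reference age; grade 3 is reserved
    for the top RPv tail. Survival times are exponential with group- (and
    RPv-) specific hazards, administratively censored at the follow-up cap.
    """
    lp = config.symptomatic_slope_per_pct * (rpv_max_pct - config.symptomatic_cutpoint_pct)
    lp += config.age_effect_logit * float(age >= config.age_reference_years)
    symptomatic = bool(rng.random() < expit(lp))
    if symptomatic:
        grade = 3 if rpv_max_pct > config.grade3_rpv_pct else 2
    else:
        grade = 1

    if treatment_group is None:
        w = np.asarray(config.treatment_weights) / np.sum(config.treatment_weights)
        treatment_group = str(rng.choice(config.treatment_groups, p=w))

    survival: dict[str, tuple[float, bool]] = {}
    for endpoint, lam in config.baseline_hazards_per_day.items():
        hazard = lam
        if endpoint == "LRPFS" and treatment_group.startswith("chemo"):
            hazard *= config.lrpfs_hr_chemo
        if endpoint == "OS" and rpv_max_pct > config.symptomatic_cutpoint_pct:
            hazard *= config.os_hr_high_rpv
        t = rng.exponential(1.0 / hazard)
        event = t <= config.followup_cap_days
        survival[endpoint] = (min(t, config.followup_cap_days), event)

    return grade, symptomatic, lp, treatment_group, survival


def _scan_schedule(config: GeneratorConfig, rng: np.random.Generator) -> list[int]:
    days = [int(rng.integers(config.first_scan_day_range[0],
                             config.first_scan_day_range[1] + 1))]
    if rng.random() < config.p_second_scan:
        days.append(days[-1] + int(rng.integers(*config.scan_gap_day_range)))
        if rng.random() < config.p_third_scan:
            days.append(days[-1] + int(rng.integers(*config.scan_gap_day_range)))
    return days


def generate_patient(
    config: GeneratorConfig, seed_seq: np.random.SeedSequence, patient_id: str
) -> SyntheticPatient:
    """One fully simulated patient, deterministic under the seed sequence."""
    rng = np.random.default_rng(seed_seq)
    dose, lung = make_phantom(config, rng)
    lung_cc = structure_volume_cc(lung)

    severity = float(
        np.exp(np.log(config.severity_median) + config.severity_sigma * rng.normal())
    )
    low_dose = bool(rng.random() < config.low_dose_lesion_rate)
    theta = 2.0 if low_dose else config.theta_gy

    days = _scan_schedule(config, rng)
    factors = rng.uniform(*config.scan_factor_range, size=len(days))
    factors[rng.integers(len(days))] = 1.0  # RPv peaks at a random scan

    lesions = [
        sow_lesion(dose, lung, config, rng, severity=severity * f, theta_gy=theta)
        for f in factors
    ]
    rpvs = [rpv(m, lung_cc) for m in lesions]
    rpv_max_pct = 100.0 * max(rpvs)

    age = int(rng.integers(config.age_range_years[0], config.age_range_years[1] + 1))
    grade_max, symptomatic, lp, group, survival = assign_outcomes(
        rpv_max_pct, age, config, rng
    )

    assessments = []
    peak = max(rpvs) if max(rpvs) > 0 else 1.0
    for i, (day, r) in enumerate(zip(days, rpvs), start=1):
        if grade_max >= 2:
            g = grade_max if r >= 0.7 * peak else grade_max - 1
        else:
            g = grade_max
        assessments.append(RPAssessment(scan_index=i, day=day, grade=g, rpv=r))

    rx = float(np.asarray(dose.values).max())
    record = PatientRecord(
        patient_id=patient_id,
        age=age,
        sex="M" if rng.random() < 0.6 else "F",
        rt_dose_gy=round(rx),
        combined_treatment=group,
        assessments=assessments,
        survival=survival,
    )
    return SyntheticPatient(
        record=record,
        dose=dose,
        lung=lung,
        lesions=lesions,
        severity=severity,
        theta_gy=theta,
        symptomatic_linear_predictor=lp,
        low_dose_seeded=low_dose,
    )


def generate_cohort(config: GeneratorConfig, seed: int) -> list[SyntheticPatient]:
    """Simulate ``config.n_patients`` phantom patients from one seed."""
    config.validate()
    children = np.random.SeedSequence(seed).spawn(config.n_patients)
    return [
        generate_patient(config, child, f"P{i:04d}")
        for i, child in enumerate(children, start=1)
    ]


def cohort_table(
    patients: list[SyntheticPatient],
    levels: tuple[int, ...] = DEFAULT_LEVELS_GY,
) -> CohortTable:
    """Run the volumetrics pipeline on simulated patients.

    DVH metrics, RPv max, and lesion coverage curves are computed by the
    same code paths used for real data (not read from generator
    bookkeeping); the coverage curve is taken at the scan attaining RPv max.
    """
    n = len(patients)
    vx_matrix = np.zeros((n, len(levels)))
    cov_matrix = np.zeros((n, len(levels)))
    rpv_max = np.zeros(n)
    grade_max = np.zeros(n, dtype=int)
    mld = np.zeros(n)
    age = np.zeros(n)
    sympt = np.zeros(n, dtype=bool)
    groups = []
    for i, pt in enumerate(patients):
        dvh = compute_dvh(pt.dose, pt.lung, structure_label="lung")
        vx_matrix[i] = [dvh.vx(x) for x in levels]
        mld[i] = dvh.mean_dose_gy
        derived = derive_rp(pt.record.assessments)
        rpv_max[i] = 100.0 * derived.rpv_max
        grade_max[i] = derived.rp_grade_max
        sympt[i] = derived.symptomatic
        age[i] = pt.record.age
        groups.append(pt.record.combined_treatment)
        best = int(np.argmax([a.rpv for a in pt.record.assessments]))
        lesion = pt.lesions[best]
        if lesion.values.any():
            cov_matrix[i] = coverage_curve(lesion, pt.dose, levels).coverage_fraction
        else:
            cov_matrix[i] = np.nan
    return CohortTable(
        rpv_max=rpv_max,
        grade_max=grade_max,
        levels_gy=np.asarray(levels),
        vx_matrix=vx_matrix,
        coverage_matrix=cov_matrix,
        mean_lung_dose_gy=mld,
        age=age,
        symptomatic=sympt,
        treatment_group=np.asarray(groups),
    )


def sample_outcome_table(n: int, config: GeneratorConfig, seed: int):
    """Fast tabular sampler (no voxel grids) for outcome-model calibration.

    RPv max is drawn from the log-normal severity law scaled by a nominal
    moderate-dose band fraction, then ages, symptomatic status, grades and
    survival follow the same outcome model as the voxel pipeline. Intended
    for ROC/survival calibration runs where only (rpv, age, outcome) matter.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    band_pct = 4.2  # nominal % of lung in the moderate-dose band
    rpv_pct = band_pct * np.exp(
        np.log(config.severity_median) + config.severity_sigma * rng.normal(size=n)
    )
    rows = []
    for i in range(n):
        a = int(rng.integers(config.age_range_years[0], config.age_range_years[1] + 1))
        grade, symptomatic, lp, group, survival = assign_outcomes(
            float(rpv_pct[i]), a, config, rng
        )
        row = {
            "patient_id": f"S{i:05d}",
            "rpv_max_pct": float(rpv_pct[i]),
            "age": a,
            "grade_max": grade,
            "symptomatic": symptomatic,
            "treatment_group": group,
        }
        for endpoint, (t, e) in survival.items():
            row[f"{endpoint.lower()}_days"] = t
            row[f"{endpoint.lower()}_event"] = e
        rows.append(row)
    return pd.DataFrame(rows)
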