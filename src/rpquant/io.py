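"""File formats, packaged fixtures, and cohort validation.

Voxel volumes travel as NIfTI (.nii.gz) with spacing/origin taken from the
header and a JSON sidecar recording patient id, scan day and structure role
(dose | lung | lesion). Cohort tables travel as CSV: one scan-level file
(patient_id, scan_index, day, grade, rpv_percent, morphology) and one
patient-level file for covariates and survival columns.

Two published per-patient tables are packaged as fixtures: the grade-max /
interval table (71 patients) and the 26 Gy lesion-coverage table (36
grade-1 + 32 grade-2 patients). ``reproduce_reference_tables`` recomputes
the headline cohort numbers from those fixtures alone.
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from dataclasses import asdict, is_dataclass
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .rp_metrics import MORPHOLOGY_PATTERNS, PatientRecord, RPAssessment
from .volumetrics import VoxelVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_interval_fixture",
    "load_coverage_fixture",
    "reproduce_reference_tables",
    "write_manifest",
]

FIXTURE_SHA256 = {
    "table2_intervals.csv": "f485025e5b169eeb7084f3dbafa4bb1f23bf41fd4c40f029da52ae9593f66168",
    "table7_coverage.csv": "c21558955acbb9f26269d97c30ec7e1b873f86fe3de54285f7463cbe4f60dd1a",
}


# ---------------------------------------------------------------- volumes

def write_volume(
    volume: VoxelVolume,
    path: str | Path,
    patient_id: str | None = None,
    role: str | None = None,
    scan_day: int | None = None,
) -> Path:
    """Write a voxel volume as NIfTI plus a JSON sidecar with provenance."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    nib.save(img, path)
    sidecar = {
        "patient_id": patient_id,
        "role": role,
        "scan_day": scan_day,
        "spacing_mm": list(volume.spacing),
        "origin_mm": list(volume.origin),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path, as_mask: bool = False) -> tuple[VoxelVolume, dict]:
    """Read a NIfTI volume (+ sidecar if present); masks are re-binarised."""
    path = Path(path)
    img = nib.load(path)
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError(f"{path}: only axis-aligned volumes are supported")
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj, dtype=float)
    if as_mask:
        data = (data > 0.5).astype(np.uint8)
    vol = VoxelVolume(data, spacing, origin)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return vol, sidecar


# ----------------------------------------------------------- cohort CSVs

SCAN_COLUMNS = ["patient_id", "scan_index", "day", "grade", "rpv_percent", "morphology"]
PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "rt_dose_gy", "technique", "combined_treatment",
    "purpose", "treatment_site", "ptv_h_volume_cc",
    "lrpfs_days", "lrpfs_event", "pfs_days", "pfs_event", "os_days", "os_event",
]


class CohortSchemaError(ValueError):
    """A cohort CSV violates the expected schema; message carries row context."""


def write_cohort_csv(
    records: list[PatientRecord], scans_path: str | Path, patients_path: str | Path
) -> None:
    """Write scan-level and patient-level CSVs (stable-sorted by patient, scan)."""
    scan_rows, patient_rows = [], []
    for rec in records:
        for a in rec.assessments:
            scan_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "scan_index": a.scan_index,
                    "day": a.day,
                    "grade": a.grade,
                    "rpv_percent": 100.0 * a.rpv,
                    "morphology": a.morphology or "",
                }
            )
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "sex": rec.sex,
            "rt_dose_gy": rec.rt_dose_gy,
            "technique": rec.technique,
            "combined_treatment": rec.combined_treatment,
            "purpose": rec.purpose,
            "treatment_site": rec.treatment_site,
            "ptv_h_volume_cc": rec.ptv_h_volume_cc,
        }
        for endpoint in ("LRPFS", "PFS", "OS"):
            t, e = rec.survival.get(endpoint, (np.nan, False))
            row[f"{endpoint.lower()}_days"] = t
            row[f"{endpoint.lower()}_event"] = int(e)
        patient_rows.append(row)
    pd.DataFrame(scan_rows, columns=SCAN_COLUMNS).sort_values(
        ["patient_id", "scan_index"]
    ).to_csv(scans_path, index=False)
    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).sort_values(
        "patient_id"
    ).to_csv(patients_path, index=False)


def read_cohort_csv(
    scans_path: str | Path, patients_path: str | Path
) -> list[PatientRecord]:
    """Load and validate the two cohort CSVs into patient records.

    Schema violations (missing columns, grades outside 0..3, RPv outside
    [0, 100], non-increasing scan days, scans for unknown patients) raise
    ``CohortSchemaError`` with row context.
    """
    scans = pd.read_csv(scans_path)
    patients = pd.read_csv(patients_path)
    missing = [c for c in SCAN_COLUMNS if c not in scans.columns and c != "morphology"]
    missing += [c for c in ("patient_id", "age") if c not in patients.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortSchemaError(f"duplicate patient ids: {dup}")

    known = set(patients["patient_id"])
    records: dict[str, PatientRecord] = {}
    for _, row in patients.iterrows():
        survival = {}
        for endpoint in ("LRPFS", "PFS", "OS"):
            tcol, ecol = f"{endpoint.lower()}_days", f"{endpoint.lower()}_event"
            if tcol in patients.columns and pd.notna(row.get(tcol)):
                survival[endpoint] = (float(row[tcol]), bool(row[ecol]))
        records[row["patient_id"]] = PatientRecord(
            patient_id=row["patient_id"],
            age=float(row["age"]),
            sex=str(row.get("sex", "")),
            rt_dose_gy=float(row.get("rt_dose_gy", np.nan)),
            technique=str(row.get("technique", "")),
            combined_treatment=str(row.get("combined_treatment", "")),
            purpose=str(row.get("purpose", "")),
            treatment_site=str(row.get("treatment_site", "")),
            ptv_h_volume_cc=(
                float(row["ptv_h_volume_cc"])
                if pd.notna(row.get("ptv_h_volume_cc"))
                else None
            ),
            survival=survival,
        )

    for idx, row in scans.sort_values(["patient_id", "scan_index"]).iterrows():
        pid = row["patient_id"]
        if pid not in known:
            raise CohortSchemaError(f"scans row {idx}: unknown patient id {pid!r}")
        morph = row.get("morphology")
        morph = morph if isinstance(morph, str) and morph in MORPHOLOGY_PATTERNS else None
        try:
            assessment = RPAssessment(
                scan_index=int(row["scan_index"]),
                day=int(row["day"]),
                grade=int(row["grade"]),
                rpv=float(row["rpv_percent"]) / 100.0,
                morphology=morph,
            )
        except (ValueError, TypeError) as err:
            raise CohortSchemaError(f"scans row {idx} (patient {pid}): {err}") from err
        rec = records[pid]
        if rec.assessments and assessment.day <= rec.assessments[-1].day:
            raise CohortSchemaError(
                f"scans row {idx} (patient {pid}): non-increasing scan days"
            )
        rec.assessments.append(assessment)
    return list(records.values())


# -------------------------------------------------------------- fixtures

def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("rpquant.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_interval_fixture() -> pd.DataFrame:
    """Per-patient grade max and intervals to each follow-up scan (71 rows)."""
    return _load_fixture("table2_intervals.csv")


def load_coverage_fixture() -> pd.DataFrame:
    """Per-patient 26 Gy lesion-coverage percentages, grades 1-2 (68 rows)."""
    return _load_fixture("table7_coverage.csv")


def reproduce_reference_tables() -> pd.DataFrame:
    """Recompute the headline cohort numbers from the packaged fixtures.

    Returns a comparison table (quantity, computed, reference) covering the
    grade-max distribution, symptomatic and grade-3 interval ranges, and
    the 26 Gy coverage pass counts/fractions per grade.
    """
    t2 = load_interval_fixture()
    t7 = load_coverage_fixture()

    rows = []

    def add(quantity: str, computed, reference) -> None:
        rows.append({"quantity": quantity, "computed": computed, "reference": reference})

    n = len(t2)
    for grade, ref_pct in ((1, 51), (2, 45), (3, 4)):
        pct = round(100.0 * (t2["grade_max"] == grade).sum() / n)
        add(f"grade {grade} proportion (%)", pct, ref_pct)

    sympt = t2.loc[t2["grade_max"] >= 2, "interval_max"]
    add("symptomatic interval min (days)", int(sympt.min()), 24)
    add("symptomatic interval max (days)", int(sympt.max()), 190)
    g3 = t2.loc[t2["grade_max"] == 3, "interval_max"]
    add("grade-3 interval min (days)", int(g3.min()), 27)
    add("grade-3 interval max (days)", int(g3.max()), 70)
    first = t2["interval_rp1"]
    add("first scan day min", int(first.min()), 5)
    add("first scan day max", int(first.max()), 190)

    for grade, (ref_count, ref_pct) in ((1, (29, 80.6)), (2, (26, 81.3))):
        sub = t7.loc[t7["grade"] == grade, "coverage_percent"]
        passes = int((sub >= 80.0).sum())
        add(f"grade-{grade} pass count at 26 Gy (coverage >= 80%)", passes, ref_count)
        # half-up to one decimal, the table-reporting convention
        frac = Decimal(str(100.0 * passes / len(sub))).quantize(
            Decimal("0.1"), ROUND_HALF_UP
        )
        add(f"grade-{grade} pass fraction at 26 Gy (%)", float(frac), ref_pct)
    return pd.DataFrame(rows)


# -------------------------------------------------------------- manifest

def write_manifest(out_dir: str | Path, config, seed: int | None, inputs: dict) -> Path:
    """Write a reproducibility manifest (config, seed, version, input hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for label, p in inputs.items():
        p = Path(p)
        if p.exists():
            checksums[label] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package": "rpquant",
        "version": __version__,
        "seed": seed,
        "config": asdict(config) if is_dataclass(config) else config,
        "input_sha256": checksums,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
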