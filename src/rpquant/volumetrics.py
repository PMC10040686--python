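"""Voxel-grid geometry: volumes, DVH metrics, RPv and isodose-coverage curves.

All quantities are computed directly from voxel doses by inclusive
thresholding (``dose >= x``); histogram bins exist only for plotting and
export. Grids are axis-aligned with the origin at the center of voxel
(0, 0, 0); no oblique orientation matrices are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "VoxelVolume",
    "DVHCurve",
    "CoverageCurve",
    "GeometryError",
    "EmptyStructureError",
    "resample_to_grid",
    "structure_volume_cc",
    "compute_dvh",
    "vx",
    "rpv",
    "coverage_curve",
    "DEFAULT_LEVELS_GY",
]

#: Integer isodose levels scanned by the coverage analysis, in Gy.
DEFAULT_LEVELS_GY = tuple(range(1, 67))


class GeometryError(ValueError):
    """Invalid or mismatched voxel-grid geometry."""


class EmptyStructureError(ValueError):
    """A structure mask required to be non-empty contains no voxels."""


@dataclass(frozen=True)
class VoxelVolume:
    """Axis-aligned 3D scalar or binary grid.

    Parameters
    ----------
    values
        3D array; absorbed dose in Gy (non-negative, finite) or a binary
        mask in {0, 1}.
    spacing
        Voxel size ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        Physical position in mm of the *center* of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={arr.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of a single voxel in cc (mm^3 / 1000)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def same_geometry(self, other: "VoxelVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def validate_dose(self) -> "VoxelVolume":
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(v < 0):
            raise ValueError("dose grid contains negative values")
        return self

    def validate_mask(self) -> "VoxelVolume":
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        return self

    def mask_array(self) -> np.ndarray:
        self.validate_mask()
        return np.asarray(self.values, dtype=bool)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``cum_volume_fraction[i]`` is the fraction of the structure receiving at
    least ``dose_edges[i]`` Gy. ``vx`` evaluates V(x) from the retained voxel
    doses, so it is exact regardless of the bin width.
    """

    structure_label: str
    dose_edges: np.ndarray
    cum_volume_fraction: np.ndarray
    total_volume_cc: float
    mean_dose_gy: float
    voxel_doses_gy: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def vx(self, x: float) -> float:
        """Percentage of structure volume receiving >= ``x`` Gy."""
        return vx(self, x)


@dataclass(frozen=True)
class CoverageCurve:
    """Fraction of a lesion's volume inside each isodose region.

    ``coverage_fraction[i]`` is the fraction of lesion voxels with dose >=
    ``levels_gy[i]``; it is non-increasing in the level.
    """

    levels_gy: np.ndarray
    coverage_fraction: np.ndarray

    def at(self, level: float) -> float:
        idx = np.nonzero(np.asarray(self.levels_gy) == level)[0]
        if idx.size == 0:
            raise KeyError(f"level {level} Gy not in coverage curve")
        return float(self.coverage_fraction[idx[0]])


def _world_to_index(points: np.ndarray, volume: VoxelVolume) -> np.ndarray:
    return (points - np.asarray(volume.origin)) / np.asarray(volume.spacing)


def resample_to_grid(
    source: VoxelVolume,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    shape: tuple[int, int, int],
    mode: str = "trilinear",
) -> tuple[VoxelVolume, float]:
    """Resample ``source`` onto a new axis-aligned grid.

    ``mode`` is ``"trilinear"`` for dose and ``"nearest"`` for masks. Target
    voxels whose centers fall outside the source extent are set to 0; the
    second return value is the fraction of such out-of-field voxels.
    """
    if any(s <= 0 for s in spacing):
        raise GeometryError(f"target spacing must be positive, got {spacing}")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"mode must be 'trilinear' or 'nearest', got {mode!r}")

    tgt_spacing = np.asarray(spacing, dtype=float)
    tgt_origin = np.asarray(origin, dtype=float)
    if (
        source.shape == tuple(shape)
        and np.allclose(source.spacing, tgt_spacing)
        and np.allclose(source.origin, tgt_origin)
    ):
        return VoxelVolume(source.values.copy(), tuple(spacing), tuple(origin)), 0.0

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * tgt_spacing + tgt_origin
    idx = _world_to_index(world.reshape(-1, 3), source)

    # voxel centers beyond the outermost source centers count as out of field
    upper = np.asarray(source.shape) - 1
    out = np.any((idx < -1e-9) | (idx > upper + 1e-9), axis=1)

    order = 1 if mode == "trilinear" else 0
    vals = map_coordinates(
        np.asarray(source.values, dtype=float), idx.T, order=order, mode="constant", cval=0.0
    )
    vals[out] = 0.0
    resampled = vals.reshape(shape)
    if mode == "nearest":
        resampled = resampled.astype(source.values.dtype)
    return VoxelVolume(resampled, tuple(spacing), tuple(origin)), float(out.mean())


def structure_volume_cc(mask: VoxelVolume) -> float:
    """Total volume of a binary structure in cc (voxel count x voxel volume)."""
    m = mask.mask_array()
    return float(m.sum()) * mask.voxel_volume_cc


def compute_dvh(
    dose: VoxelVolume,
    mask: VoxelVolume,
    bin_width_gy: float = 0.1,
    structure_label: str = "structure",
) -> DVHCurve:
    """Cumulative DVH of ``mask`` under ``dose`` (shared geometry required)."""
    if not dose.same_geometry(mask):
        raise GeometryError("dose and mask must share geometry; resample first")
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    dose.validate_dose()
    m = mask.mask_array()
    if not m.any():
        raise EmptyStructureError(f"structure {structure_label!r} is empty")

    doses = np.sort(np.asarray(dose.values, dtype=float)[m])
    n = doses.size
    n_bins = int(np.ceil(doses[-1] / bin_width_gy)) + 1 if doses[-1] > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    # fraction of voxels with dose >= edge (inclusive threshold)
    cum = 1.0 - np.searchsorted(doses, edges, side="left") / n
    return DVHCurve(
        structure_label=structure_label,
        dose_edges=edges,
        cum_volume_fraction=cum,
        total_volume_cc=n * mask.voxel_volume_cc,
        mean_dose_gy=float(doses.mean()),
        voxel_doses_gy=doses,
    )


def vx(dvh: DVHCurve, x: float) -> float:
    """V(x): percentage of structure volume receiving >= ``x`` Gy."""
    if x < 0:
        raise ValueError("dose level must be non-negative")
    if dvh.voxel_doses_gy is not None:
        doses = dvh.voxel_doses_gy
        frac = 1.0 - np.searchsorted(doses, x, side="left") / doses.size
        return 100.0 * float(frac)
    i = int(np.searchsorted(dvh.dose_edges, x, side="right")) - 1
    if i >= dvh.cum_volume_fraction.size:
        return 0.0
    return 100.0 * float(dvh.cum_volume_fraction[i])


def rpv(lesion_mask: VoxelVolume, total_lung_volume_cc: float) -> float:
    """Lesion-to-lung volume ratio (RPv), as a fraction.

    RPv is the volume of a radiologically identified pneumonitis lesion
    divided by the total lung volume of the planning CT.
    """
    if total_lung_volume_cc <= 0:
        raise ValueError("total lung volume must be positive")
    return structure_volume_cc(lesion_mask) / total_lung_volume_cc


def coverage_curve(
    lesion_mask: VoxelVolume,
    dose: VoxelVolume,
    levels: tuple[int, ...] = DEFAULT_LEVELS_GY,
) -> CoverageCurve:
    """Isodose coverage of a lesion: fraction of lesion voxels with dose >= d.

    The curve answers, per candidate level d, how much of the lesion lies
    inside the d-Gy isodose region — the quantity behind the 26 Gy rule for
    recognising a lesion as radiation-induced.
    """
    if not dose.same_geometry(lesion_mask):
        raise GeometryError("dose and lesion mask must share geometry; resample first")
    dose.validate_dose()
    m = lesion_mask.mask_array()
    if not m.any():
        raise EmptyStructureError("lesion mask is empty")
    doses = np.sort(np.asarray(dose.values, dtype=float)[m])
    lv = np.asarray(levels, dtype=float)
    frac = 1.0 - np.searchsorted(doses, lv, side="left") / doses.size
    return CoverageCurve(levels_gy=np.asarray(levels), coverage_fraction=frac)
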