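"""Geometry engine checked against brute-force voxel enumeration."""

import numpy as np
import pytest

from rpquant import (
    VoxelVolume,
    compute_dvh,
    coverage_curve,
    resample_to_grid,
    rpv,
    structure_volume_cc,
    vx,
)
from rpquant.volumetrics import EmptyStructureError, GeometryError

from conftest import make_volume


def trilinear_oracle(values, spacing, origin, point):
    """Direct closed-form trilinear interpolation at one physical point."""
    f = (np.asarray(point) - np.asarray(origin)) / np.asarray(spacing)
    i0 = np.floor(f).astype(int)
    t = f - i0
    acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = np.minimum(i0 + [dx, dy, dz], np.array(values.shape) - 1)
                w = (
                    (t[0] if dx else 1 - t[0])
                    * (t[1] if dy else 1 - t[1])
                    * (t[2] if dz else 1 - t[2])
                )
                acc += w * values[tuple(idx)]
    return acc


class TestResample:
    def test_identity_geometry_is_bitwise(self, rng):
        vol = make_volume(rng.uniform(0, 60, (6, 5, 4)), spacing=(2, 2, 3))
        out, oof = resample_to_grid(vol, (2, 2, 3), (0, 0, 0), (6, 5, 4))
        assert oof == 0.0
        np.testing.assert_array_equal(out.values, vol.values)

    def test_constant_dose_on_finer_interior_grid(self):
        vol = make_volume(np.full((8, 8, 8), 10.0), spacing=(4, 4, 4))
        out, oof = resample_to_grid(vol, (2, 2, 2), (2, 2, 2), (10, 10, 10))
        assert oof == 0.0
        np.testing.assert_allclose(out.values, 10.0)

    def test_trilinear_matches_closed_form_oracle(self, rng):
        src = make_volume(rng.uniform(0, 66, (8, 8, 8)), spacing=(3, 3, 3))
        out, _ = resample_to_grid(src, (1.5, 1.5, 1.5), (0, 0, 0), (15, 15, 15))
        for idx in rng.integers(0, 15, size=(40, 3)):
            point = idx * 1.5
            expected = trilinear_oracle(src.values, src.spacing, src.origin, point)
            assert abs(out.values[tuple(idx)] - expected) < 1e-9

    def test_out_of_field_voxels_are_zero_and_counted(self):
        vol = make_volume(np.full((4, 4, 4), 5.0), spacing=(1, 1, 1))
        out, oof = resample_to_grid(vol, (1, 1, 1), (0, 0, -2), (4, 4, 6))
        assert oof == pytest.approx(2 / 6)
        assert np.all(out.values[:, :, :2] == 0)
        np.testing.assert_allclose(out.values[:, :, 2:], 5.0)

    def test_nearest_preserves_mask_values(self, rng):
        mask = make_volume((rng.random((6, 6, 6)) < 0.5).astype(np.uint8))
        out, _ = resample_to_grid(mask, (0.5, 0.5, 0.5), (0, 0, 0), (11, 11, 11),
                                  mode="nearest")
        assert set(np.unique(out.values)) <= {0, 1}

    def test_invalid_geometry_rejected(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(GeometryError):
            resample_to_grid(vol, (0, 1, 1), (0, 0, 0), (3, 3, 3))
        with pytest.raises(GeometryError):
            VoxelVolume(np.zeros((3, 3, 3)), (1, -1, 1))


class TestStructureVolume:
    def test_empty_mask_is_zero(self):
        assert structure_volume_cc(make_volume(np.zeros((5, 5, 5)))) == 0.0

    def test_thousand_unit_voxels_is_one_cc(self):
        m = np.zeros((10, 10, 10))
        m[:] = 1
        assert structure_volume_cc(make_volume(m)) == pytest.approx(1.0)

    def test_random_mask_matches_counting_oracle(self, rng):
        m = (rng.random((9, 7, 5)) < 0.4).astype(np.uint8)
        vol = make_volume(m, spacing=(1.5, 2.0, 3.0))
        assert structure_volume_cc(vol) == pytest.approx(m.sum() * 1.5 * 2 * 3 / 1000)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            structure_volume_cc(make_volume(np.full((2, 2, 2), 2.0)))


class TestDVH:
    def test_uniform_dose(self):
        dose = make_volume(np.full((5, 5, 5), 10.0))
        mask = make_volume(np.ones((5, 5, 5), dtype=np.uint8))
        dvh = compute_dvh(dose, mask)
        assert dvh.mean_dose_gy == pytest.approx(10.0)
        assert dvh.vx(10) == pytest.approx(100.0)  # inclusive threshold
        assert dvh.vx(10.1) == 0.0
        assert dvh.vx(0) == pytest.approx(100.0)

    def test_two_equal_regions(self):
        values = np.zeros((4, 4, 4))
        values[:2] = 20.0
        values[2:] = 40.0
        dvh = compute_dvh(make_volume(values),
                          make_volume(np.ones((4, 4, 4), dtype=np.uint8)))
        assert dvh.vx(26) == pytest.approx(50.0)
        assert dvh.mean_dose_gy == pytest.approx(30.0)

    def test_vx_matches_counting_oracle_at_every_level(self, random_dose_and_masks):
        dose, lung, _ = random_dose_and_masks
        dvh = compute_dvh(dose, lung)
        m = lung.values.astype(bool)
        for x in range(0, 67):
            expected = 100.0 * np.mean(dose.values[m] >= x)
            assert dvh.vx(x) == pytest.approx(expected, abs=1e-12)

    def test_curve_invariants(self, random_dose_and_masks):
        dose, lung, _ = random_dose_and_masks
        dvh = compute_dvh(dose, lung, bin_width_gy=0.5)
        assert np.all(np.diff(dvh.cum_volume_fraction) <= 1e-15)
        assert dvh.cum_volume_fraction[0] == 1.0
        differential = -np.diff(np.append(dvh.cum_volume_fraction, 0.0))
        assert differential.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_dose_matches_riemann_sum_of_curve(self, random_dose_and_masks):
        dose, lung, _ = random_dose_and_masks
        w = 0.1
        dvh = compute_dvh(dose, lung, bin_width_gy=w)
        riemann = w * dvh.cum_volume_fraction[1:].sum()  # sum over edges w, 2w, ...
        assert abs(riemann - dvh.mean_dose_gy) <= w

    def test_empty_structure_and_geometry_mismatch(self):
        dose = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(EmptyStructureError):
            compute_dvh(dose, make_volume(np.zeros((3, 3, 3), dtype=np.uint8)))
        other = make_volume(np.ones((3, 3, 3), dtype=np.uint8), spacing=(2, 2, 2))
        with pytest.raises(GeometryError):
            compute_dvh(dose, other)


class TestRPv:
    def test_known_ratio(self):
        lesion = np.zeros((10, 10, 10), dtype=np.uint8)
        lesion[:3] = 1  # 300 voxels at 1 mm^3 -> 0.3 cc
        assert rpv(make_volume(lesion), 3.0) == pytest.approx(0.10)

    def test_empty_lesion_is_zero(self):
        assert rpv(make_volume(np.zeros((4, 4, 4), dtype=np.uint8)), 100.0) == 0.0

    def test_composition_with_structure_volume(self, random_dose_and_masks):
        _, lung, lesion = random_dose_and_masks
        lung_cc = structure_volume_cc(lung)
        assert rpv(lesion, lung_cc) == pytest.approx(
            structure_volume_cc(lesion) / lung_cc
        )

    def test_zero_lung_volume_rejected(self):
        with pytest.raises(ValueError):
            rpv(make_volume(np.zeros((2, 2, 2), dtype=np.uint8)), 0.0)


class TestCoverage:
    def test_lesion_inside_high_dose_region(self):
        dose = make_volume(np.full((5, 5, 5), 30.0))
        lesion = np.zeros((5, 5, 5), dtype=np.uint8)
        lesion[2, 2, 2] = 1
        assert coverage_curve(make_volume(lesion), dose).at(26) == 1.0

    def test_half_covered_by_construction(self):
        values = np.zeros((4, 4, 4))
        values[:2] = 30.0
        lesion = np.zeros((4, 4, 4), dtype=np.uint8)
        lesion[1] = 1
        lesion[2] = 1
        curve = coverage_curve(make_volume(lesion), make_volume(values))
        assert curve.at(26) == pytest.approx(0.5)

    def test_matches_counting_oracle_and_monotone(self, random_dose_and_masks):
        dose, _, lesion = random_dose_and_masks
        curve = coverage_curve(lesion, dose)
        m = lesion.values.astype(bool)
        for d, frac in zip(curve.levels_gy, curve.coverage_fraction):
            expected = np.mean(dose.values[m] >= d)
            assert frac == pytest.approx(expected, abs=1e-12)
        assert np.all(np.diff(curve.coverage_fraction) <= 1e-15)

    def test_empty_lesion_rejected(self):
        dose = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(EmptyStructureError):
            coverage_curve(make_volume(np.zeros((3, 3, 3), dtype=np.uint8)), dose)


def test_vx_without_voxel_doses_falls_back_to_bins(random_dose_and_masks):
    dose, lung, _ = random_dose_and_masks
    dvh = compute_dvh(dose, lung, bin_width_gy=0.1)
    import dataclasses

    binned = dataclasses.replace(dvh, voxel_doses_gy=None)
    for x in (0, 10, 26, 40):
        assert vx(binned, x) == pytest.approx(dvh.vx(x), abs=0.5)
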