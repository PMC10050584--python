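"""Discretization, first-order and shape features."""

import numpy as np
import pytest

from ptpdomics.core import Mask3D
from ptpdomics.features import discretize, first_order_features, shape_features
from ptpdomics.features.shape import face_surface_area_mm2

from .conftest import volume_and_mask


class TestDiscretize:
    def test_floor_arithmetic(self):
        vol, voi = volume_and_mask(np.array([[[0.0, 24.9], [25.0, 50.0]]]))
        grid = discretize(vol, voi, 25.0)
        np.testing.assert_array_equal(grid.levels, [[[1, 1], [2, 3]]])
        assert grid.n_levels == 3

    def test_constant_region_single_level(self):
        vol, voi = volume_and_mask(np.full((2, 2, 2), 7.3))
        grid = discretize(vol, voi, 25.0)
        assert grid.n_levels == 1
        assert set(np.unique(grid.levels)) == {1}

    def test_halving_width_never_decreases_level_count(self):
        rng = np.random.default_rng(1)
        vol, voi = volume_and_mask(rng.uniform(0, 100, (3, 3, 3)))
        for width in (40.0, 20.0, 10.0, 5.0):
            coarse = discretize(vol, voi, width).n_levels
            fine = discretize(vol, voi, width / 2).n_levels
            assert fine >= coarse

    def test_shift_invariance(self):
        """Adding a constant leaves min-referenced bins unchanged."""
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 50, (3, 4, 2))
        vol1, voi = volume_and_mask(values)
        vol2, _ = volume_and_mask(values + 123.4)
        np.testing.assert_array_equal(
            discretize(vol1, voi, 5.0).levels, discretize(vol2, voi, 5.0).levels
        )


class TestFirstOrder:
    def test_hand_arithmetic(self):
        vol, voi = volume_and_mask(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
        f = first_order_features(vol, voi, bin_width=1.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Energy"] == pytest.approx(30.0)
        assert f["Range"] == pytest.approx(3.0)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30.0 / 4))
        assert f["Variance"] == pytest.approx(1.25)
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_region(self):
        vol, voi = volume_and_mask(np.full((2, 3, 2), 5.0))
        f = first_order_features(vol, voi)
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_total_energy_scales_with_voxel_volume(self):
        values = np.arange(8.0).reshape(2, 2, 2)
        vol1, voi1 = volume_and_mask(values, spacing=(1.0, 1.0, 1.0))
        vol2, voi2 = volume_and_mask(values, spacing=(2.0, 2.0, 2.0))
        f1 = first_order_features(vol1, voi1)
        f2 = first_order_features(vol2, voi2)
        assert f2["TotalEnergy"] == pytest.approx(8.0 * f1["TotalEnergy"])
        assert f2["Energy"] == pytest.approx(f1["Energy"])


def digital_ball(radius_vox: int, spacing=(1.0, 1.0, 1.0)) -> Mask3D:
    n = 2 * radius_vox + 3
    c = n // 2
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    arr = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    return Mask3D(arr, spacing)


class TestShape:
    def test_ball_sphericity_near_one(self):
        """A digital ball approaches the analytic sphericity limit of 1."""
        f = shape_features(digital_ball(15))
        assert 0.95 <= f["Sphericity"] <= 1.0
        assert f["Elongation"] == pytest.approx(1.0, abs=0.02)
        assert f["Flatness"] == pytest.approx(1.0, abs=0.02)

    def test_ball_volume_diameter_and_area(self):
        r = 10
        f = shape_features(digital_ball(r))
        assert f["VoxelVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
        assert f["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.08)
        assert f["SurfaceArea"] == pytest.approx(4 * np.pi * r**2, rel=0.05)

    def test_rod_matches_closed_form_moments(self):
        """1x1x10 rod: covariance eigenvalues are (n^2-1)/12 * s^2 along
        the rod and 0 across it."""
        arr = np.zeros((5, 5, 12), dtype=bool)
        arr[2, 2, 1:11] = True
        f = shape_features(Mask3D(arr, (1.0, 1.0, 1.0)))
        lam = (10**2 - 1) / 12.0
        assert f["MajorAxisLength"] == pytest.approx(4 * np.sqrt(lam))
        assert f["LeastAxisLength"] == pytest.approx(0.0, abs=1e-9)
        assert f["Flatness"] == pytest.approx(0.0, abs=1e-9)
        assert f["Elongation"] == pytest.approx(0.0, abs=1e-9)

    def test_cube_face_surface_area_exact(self):
        """Face counting is exact for an axis-aligned cuboid and bounds
        the mesh estimate from above."""
        arr = np.zeros((6, 6, 6), dtype=bool)
        arr[1:5, 1:5, 1:5] = True
        m_iso = Mask3D(arr, (1.0, 1.0, 1.0))
        assert face_surface_area_mm2(m_iso) == pytest.approx(6 * 16.0)
        # anisotropic spacing: physical cuboid 8x4x4 mm
        m_aniso = Mask3D(arr, (2.0, 1.0, 1.0))
        assert face_surface_area_mm2(m_aniso) == pytest.approx(2 * 16.0 + 4 * 32.0)
        mesh_area = shape_features(m_iso)["SurfaceArea"]
        assert mesh_area <= face_surface_area_mm2(m_iso) + 1e-9

    def test_single_voxel_fallbacks(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[1, 1, 1] = True
        f = shape_features(Mask3D(arr, (1.0, 1.0, 1.0)))
        assert f["VoxelVolume"] == 1.0
        assert f["SurfaceArea"] > 0.0
        assert np.isfinite(f["Sphericity"])
        assert f["Elongation"] == 1.0 and f["Flatness"] == 1.0
        assert f["Maximum3DDiameter"] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        arr = np.zeros((8, 8, 8), dtype=bool)
        arr[2:5, 2:6, 3:5] = True
        f1 = shape_features(Mask3D(arr, (1.0, 2.0, 1.0)))
        f2 = shape_features(Mask3D(np.roll(arr, (1, 1, 2), (0, 1, 2)), (1.0, 2.0, 1.0)))
        for key in f1:
            assert f1[key] == pytest.approx(f2[key], rel=1e-6), key
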