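import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from discqmri.geometry import (
    DegenerateGeometryError,
    DiscSegmentation,
    extract_np,
    principal_axes,
    standardize_disc,
)


def rect_coords(n_ap=21, n_si=9):
    ap, si = np.meshgrid(np.arange(n_ap, dtype=float), np.arange(n_si, dtype=float))
    return np.column_stack([ap.ravel(), si.ravel()])


def rotate(coords, deg):
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = coords.mean(axis=0)
    return (coords - c) @ R.T + c


def ellipse_mask_volume(a=24.0, b=7.0, deg=0.0, shape=(1, 64, 64), label=1):
    """Analytically rotated filled ellipse (no resampling)."""
    _, nr, nc = shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    th = np.deg2rad(deg)
    dx = cols - nc / 2
    dy = rows - nr / 2
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    lab = np.zeros(shape, dtype=np.int16)
    lab[0][(u / a) ** 2 + (v / b) ** 2 <= 1.0] = label
    return lab


class TestPrincipalAxes:
    def test_axis_aligned_rectangle_identity(self):
        R, evals, degenerate = principal_axes(rect_coords())
        np.testing.assert_allclose(R, np.eye(2), atol=1e-9)
        assert evals[0] > evals[1]
        assert not degenerate

    @pytest.mark.parametrize("deg", [10.0, 30.0, 45.0, 80.0])
    def test_rotated_rectangle_angle_recovery(self, deg):
        R, _, _ = principal_axes(rotate(rect_coords(), deg))
        recovered = np.degrees(np.arctan2(R[1, 0], R[0, 0])) % 180.0
        assert recovered == pytest.approx(deg % 180.0, abs=0.5)

    def test_circle_isotropic_identity_with_flag(self):
        xs, ys = np.meshgrid(np.arange(-10, 11), np.arange(-10, 11))
        sel = xs**2 + ys**2 <= 100
        R, _, degenerate = principal_axes(np.column_stack([xs[sel], ys[sel]]).astype(float))
        assert degenerate
        np.testing.assert_allclose(R, np.eye(2))

    def test_too_few_or_collinear_raise(self):
        with pytest.raises(DegenerateGeometryError):
            principal_axes(np.array([[0.0, 0.0], [1.0, 1.0]]))
        line = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            principal_axes(line)

    def test_major_axis_sign_points_anteroposterior(self):
        R, _, _ = principal_axes(rotate(rect_coords(), 30.0))
        assert R[0, 0] > 0  # AP component of the major axis is positive


class TestStandardizeDisc:
    def test_single_slice_matches_principal_axes_composition(self):
        lab = np.zeros((1, 9, 21), dtype=np.int16)
        lab[0, :, :] = 1
        seg = DiscSegmentation(lab)
        std = standardize_disc(seg, "L1L2")
        coords = rect_coords()
        R, _, _ = principal_axes(coords)
        expected = (coords - coords.mean(axis=0)) @ R
        np.testing.assert_allclose(np.sort(std.coords_std, axis=0), np.sort(expected, axis=0), atol=1e-9)
        assert np.allclose(std.coords_std.mean(axis=0), 0.0, atol=1e-9)

    def test_four_identical_slices_pool_to_same_frame(self):
        lab1 = np.zeros((1, 9, 21), dtype=np.int16)
        lab1[0, 2:7, 3:18] = 2
        lab4 = np.tile(lab1, (4, 1, 1))
        std1 = standardize_disc(DiscSegmentation(lab1), "L2L3")
        std4 = standardize_disc(DiscSegmentation(lab4), "L2L3")
        np.testing.assert_allclose(std4.rotation, std1.rotation, atol=1e-12)
        assert std4.coords_std.shape[0] == 4 * std1.coords_std.shape[0]

    def test_shifted_slice_centroid_matches_direct_moment_oracle(self):
        lab = np.zeros((4, 9, 30), dtype=np.int16)
        lab[:, 2:7, 3:24] = 3
        lab[3] = np.roll(lab[3], 2, axis=1)  # one slice shifted 2 voxels AP
        seg = DiscSegmentation(lab)
        std = standardize_disc(seg, "L3L4")
        idx = np.nonzero(lab == 3)
        pooled = np.column_stack([idx[2].astype(float), idx[1].astype(float)])  # (AP, SI)
        np.testing.assert_allclose(std.centroid_mm, pooled.mean(axis=0), atol=1e-12)
        # second moments about the centroid agree with a direct computation
        centered = pooled - pooled.mean(axis=0)
        tensor = centered.T @ centered
        evals = np.sort(np.linalg.eigvalsh(tensor))[::-1]
        np.testing.assert_allclose(np.sort(std.eigenvalues)[::-1], evals, rtol=1e-12)

    def test_missing_level_raises_lookup_error(self):
        seg = DiscSegmentation(ellipse_mask_volume(label=1))
        with pytest.raises(KeyError):
            standardize_disc(seg, "L5S1")

    def test_spacing_scales_coordinates(self):
        lab = np.zeros((1, 9, 21), dtype=np.int16)
        lab[0, :, :] = 1
        std_iso = standardize_disc(DiscSegmentation(lab), "L1L2")
        std_aniso = standardize_disc(DiscSegmentation(lab, spacing_mm=(1.0, 1.0, 2.0)), "L1L2")
        assert std_aniso.ap_extent_mm[1] == pytest.approx(2 * std_iso.ap_extent_mm[1])


class TestExtractNP:
    def test_central_40pct_of_20_columns_is_8_columns(self):
        lab = np.zeros((1, 6, 30), dtype=np.int16)
        lab[0, 1:5, 4:24] = 1
        std = standardize_disc(DiscSegmentation(lab), "L1L2")
        region = extract_np(std, 0.40)
        cols = np.unique(region.np_voxel_indices[2])
        np.testing.assert_array_equal(cols, np.arange(10, 18))

    def test_fraction_one_returns_full_disc(self):
        seg = DiscSegmentation(ellipse_mask_volume())
        std = standardize_disc(seg, "L1L2")
        region = extract_np(std, 1.0)
        assert region.n_voxels == std.coords_std.shape[0]

    @staticmethod
    def _rect_volume(deg, half_ap=19.5, half_si=4.5, n=64):
        rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        th = np.deg2rad(deg)
        u = np.cos(th) * (cols - n / 2) + np.sin(th) * (rows - n / 2)
        v = -np.sin(th) * (cols - n / 2) + np.cos(th) * (rows - n / 2)
        lab = np.zeros((1, n, n), dtype=np.int16)
        lab[0][(np.abs(u) <= half_ap) & (np.abs(v) <= half_si)] = 1
        return lab

    def test_rotated_rectangle_np_count_close_to_unrotated(self):
        n0 = extract_np(standardize_disc(DiscSegmentation(self._rect_volume(0.0)), "L1L2"), 0.40).n_voxels
        n30 = extract_np(standardize_disc(DiscSegmentation(self._rect_volume(30.0)), "L1L2"), 0.40).n_voxels
        # within one boundary row (9 voxels tall) of each other
        assert abs(n30 - n0) <= 9

    @pytest.mark.parametrize("deg", [10.0, 25.0, 45.0])
    def test_np_set_rotation_invariance_jaccard(self, deg):
        # "Up to discretization": rotating an integer lattice and rounding
        # back creates spurious collisions, so membership is matched with
        # a sub-voxel (0.75 voxel) tolerance instead of exact rounding.
        from scipy.spatial import cKDTree

        a, b = 24.0, 7.0
        seg0 = DiscSegmentation(ellipse_mask_volume(a, b, 0.0))
        seg1 = DiscSegmentation(ellipse_mask_volume(a, b, deg))
        r0 = extract_np(standardize_disc(seg0, "L1L2"), 0.40)
        r1 = extract_np(standardize_disc(seg1, "L1L2"), 0.40)
        th = np.deg2rad(deg)
        rr, cc = r1.np_voxel_indices[1].astype(float), r1.np_voxel_indices[2].astype(float)
        dx, dy = cc - 32.0, rr - 32.0
        back = np.column_stack([32.0 - np.sin(th) * dx + np.cos(th) * dy,
                                32.0 + np.cos(th) * dx + np.sin(th) * dy])
        orig = np.column_stack([r0.np_voxel_indices[1], r0.np_voxel_indices[2]]).astype(float)
        d_back, _ = cKDTree(orig).query(back)
        inter = int((d_back <= 0.75).sum())
        union = len(back) + len(orig) - inter
        assert len(orig) >= 200
        assert inter / union >= 0.9

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        f1=st_.floats(min_value=0.1, max_value=0.9),
        f2=st_.floats(min_value=0.1, max_value=0.9),
    )
    def test_np_nesting_in_fraction(self, f1, f2):
        lo, hi = sorted((f1, f2))
        seg = DiscSegmentation(ellipse_mask_volume())
        std = standardize_disc(seg, "L1L2")
        small = extract_np(std, lo)
        big = extract_np(std, hi)
        small_set = set(zip(*(a.tolist() for a in small.np_voxel_indices)))
        big_set = set(zip(*(a.tolist() for a in big.np_voxel_indices)))
        assert small_set <= big_set

    def test_convex_mask_area_fraction_in_range(self):
        seg = DiscSegmentation(ellipse_mask_volume(a=24, b=7))
        std = standardize_disc(seg, "L1L2")
        region = extract_np(std, 0.40)
        frac = region.n_voxels / std.coords_std.shape[0]
        assert std.coords_std.shape[0] >= 500
        assert 0.30 <= frac <= 0.50

    def test_bad_fraction_rejected(self):
        seg = DiscSegmentation(ellipse_mask_volume())
        std = standardize_disc(seg, "L1L2")
        for f in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                extract_np(std, f)
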