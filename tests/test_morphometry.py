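import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from icemorph.morphometry import (
    volume_fractions, vertical_profile, specific_surface_area, interface_area,
    local_thickness, thickness_distribution, mean_curvature_field,
    curvature_distribution,
)
from icemorph.volio import AIR, ICE_OUTSIDE, ICE_INSIDE, STARCH, LabelVolume
from .conftest import digit_sphere


def _labels(data, voxel_size=1.0):
    return LabelVolume(np.asarray(data, dtype=np.uint8), voxel_size)


class TestVolumeFractions:
    def test_all_air_leaves_ice_share_undefined(self):
        fr = volume_fractions(_labels(np.zeros((4, 4, 4))))
        assert fr.phi_air == 1.0
        assert fr.phi_ice_outside is None

    def test_constructed_counts(self):
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[:2] = AIR
        data[2] = ICE_INSIDE
        data[3] = STARCH
        fr = volume_fractions(_labels(data))
        assert fr.phi_air == 0.5
        assert fr.phi_ice_in_solid == 0.5
        assert fr.phi_ice_outside == 0.0

    def test_matches_generator_bookkeeping(self, fast_phantom):
        fr = volume_fractions(fast_phantom.truth)
        c = fast_phantom.truth_counts()
        assert fr.V_air == c["air"]
        assert fr.V_ice_inside == c["ice_inside"]
        assert fr.V_ice_outside == c["ice_outside"]
        assert fr.V_starch == c["starch"]

    @given(seed=st.integers(0, 200))
    def test_identities_hold_exactly(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 4, size=(12, 12, 12)).astype(np.uint8)
        fr = volume_fractions(_labels(data))
        assert fr.V_air + fr.V_ice + fr.V_starch == fr.V_total == data.size
        assert fr.V_ice_inside + fr.V_ice_outside == fr.V_ice
        assert fr.phi_air == fr.V_air / fr.V_total
        if fr.V_ice:
            assert fr.phi_ice_outside == fr.V_ice_outside / fr.V_ice
        if fr.V_ice + fr.V_starch:
            assert fr.phi_ice_in_solid == fr.V_ice / (fr.V_ice + fr.V_starch)


class TestVerticalProfile:
    def test_air_top_half_has_unit_porosity(self):
        data = np.full((10, 6, 6), STARCH, dtype=np.uint8)
        data[5:] = AIR
        prof = vertical_profile(_labels(data), "porosity", slab_vx=1)
        assert np.allclose(prof.values[5:], 1.0)
        assert np.allclose(prof.values[:5], 0.0)

    def test_full_height_slab_equals_global_fraction(self, fast_phantom):
        labels = fast_phantom.truth
        prof = vertical_profile(labels, "ice_in_solid", slab_vx=labels.shape[0])
        assert len(prof.values) == 1
        assert prof.values[0] == pytest.approx(volume_fractions(labels).phi_ice_in_solid)

    def test_empty_denominator_flagged_missing(self):
        data = np.full((4, 4, 4), AIR, dtype=np.uint8)
        prof = vertical_profile(_labels(data), "ice_in_solid", slab_vx=1)
        assert np.isnan(prof.values).all()

    def test_stationary_phantom_profile_is_flat(self, fast_phantom):
        prof = vertical_profile(fast_phantom.truth, "porosity", slab_vx=10)
        assert prof.values.std() < 0.1


class TestSpecificSurfaceArea:
    def test_sphere_area_within_5pct(self):
        sph = digit_sphere((100, 100, 100), (50, 50, 50), 20)
        area = interface_area(sph, ~sph, 1.0)
        assert area == pytest.approx(4 * np.pi * 20**2, rel=0.05)

    def test_flat_slab_ssa_within_2pct(self):
        n = 100
        data = np.zeros((n, n, n), dtype=np.uint8)
        data[: n // 2] = STARCH
        res = specific_surface_area(_labels(data, 1.0), "air", "starch")
        # one interface of n² µm² in n³ µm³ -> 1/n µm^-1 = 1000/n mm^-1
        assert res.ssa_mm == pytest.approx(1000.0 / n, rel=0.02)

    def test_no_ice_gives_zero(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        res = specific_surface_area(_labels(data), "air", "ice_outside")
        assert res.area_um2 == 0.0 and res.ssa_mm == 0.0

    def test_scale_equivariance(self):
        # same physical ball sampled at voxel sizes 1.0 and 0.5 µm
        a = digit_sphere((50, 50, 50), (25, 25, 25), 12)
        b = digit_sphere((100, 100, 100), (50, 50, 50), 24)
        ssa_a = interface_area(a, ~a, 1.0) / (50**3 * 1.0**3)
        ssa_b = interface_area(b, ~b, 0.5) / (100**3 * 0.5**3)
        assert ssa_a == pytest.approx(ssa_b, rel=0.05)

    def test_cross_check_against_marching_cubes_mesh(self):
        # smooth blob: union of two overlapping balls
        blob = digit_sphere((60, 60, 60), (26, 30, 30), 12)
        blob |= digit_sphere((60, 60, 60), (36, 30, 30), 12)
        crofton = interface_area(blob, ~blob, 1.0)
        f = ndimage.gaussian_filter(blob.astype(float), 1.2)
        verts, faces, _, _ = marching_cubes(f, 0.5)
        mesh = mesh_surface_area(verts, faces)
        assert crofton == pytest.approx(mesh, rel=0.08)


def _thickness_oracle(mask):
    """Exhaustive sphere superposition: max diameter over all covering spheres."""
    edt2 = np.rint(ndimage.distance_transform_edt(mask) ** 2).astype(np.int64)
    pts = np.argwhere(mask)
    out = np.zeros(mask.shape)
    for p in pts:
        best2 = 0
        for q in pts:
            d2 = int(((p - q) ** 2).sum())
            if d2 <= edt2[tuple(q)] and edt2[tuple(q)] > best2:
                best2 = int(edt2[tuple(q)])
        out[tuple(p)] = 2.0 * np.sqrt(best2)
    return out


class TestLocalThickness:
    def test_ball_interior_thickness_equals_diameter(self):
        ball = digit_sphere((31, 31, 31), (15, 15, 15), 10)
        vals = local_thickness(ball, 1.0).foreground_values()
        assert np.all(np.abs(vals - 21.0) <= 1.0)
        assert vals.min() == vals.max()  # every voxel sees the same largest sphere

    def test_slab_thickness_equals_slab_width(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[:, 10:20, :] = True
        vals = local_thickness(mask, 2.0).foreground_values()
        assert np.all(np.abs(vals - 10 * 2.0) <= 1 * 2.0)

    def test_empty_mask_gives_empty_map(self):
        tm = local_thickness(np.zeros((8, 8, 8), dtype=bool), 1.0)
        assert tm.foreground_values().size == 0

    @given(seed=st.integers(0, 40))
    def test_equals_exhaustive_oracle_on_small_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndimage.binary_dilation(rng.random((14, 14, 14)) < 0.06, iterations=2)
        got = local_thickness(mask, 1.0).data
        assert np.allclose(got, _thickness_oracle(mask))

    def test_bounded_by_global_max_inscribed_sphere(self, fast_phantom):
        mask = fast_phantom.truth.mask("ice_outside")
        edt = ndimage.distance_transform_edt(mask)
        tm = local_thickness(mask, fast_phantom.truth.voxel_size)
        assert tm.data.max() <= 2 * edt.max() * fast_phantom.truth.voxel_size + 1e-9


class TestThicknessDistribution:
    def test_uniform_object_is_step_function(self):
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[:, 10:20, :] = True
        dist = thickness_distribution(local_thickness(mask, 1.0))
        jump = np.diff(np.concatenate([[0.0], dist.values]))
        assert jump.max() == pytest.approx(100.0)

    def test_two_ball_plateau_at_volume_share(self):
        mask = digit_sphere((60, 120, 60), (30, 30, 30), 8)
        mask |= digit_sphere((60, 120, 60), (30, 85, 30), 16)
        v1 = int(digit_sphere((60, 120, 60), (30, 30, 30), 8).sum())
        v2 = int(digit_sphere((60, 120, 60), (30, 85, 30), 16).sum())
        dist = thickness_distribution(local_thickness(mask, 1.0))
        mid = (dist.bin_edges[1:] >= 20) & (dist.bin_edges[1:] <= 30)
        assert np.allclose(dist.values[mid], 100.0 * v1 / (v1 + v2), atol=0.5)

    def test_curve_ends_at_100(self, fast_phantom):
        mask = fast_phantom.truth.mask("ice_outside")
        dist = thickness_distribution(local_thickness(mask, 2.0))
        assert dist.values[-1] == pytest.approx(100.0)
        assert np.all(np.diff(dist.values) >= 0)


class TestMeanCurvature:
    def test_spherical_pore_one_mm_diameter_is_minus_two(self):
        # air ball of radius 25 vx at 20 µm/vx -> diameter 1 mm
        pore = digit_sphere((100, 100, 100), (50, 50, 50), 25)
        fld = mean_curvature_field(~pore, voxel_size=20.0, sigma_vx=2.0)
        assert fld.area_weighted_mean == pytest.approx(-2.0, rel=0.10)

    def test_flat_interface_has_zero_curvature(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[:20] = True
        fld = mean_curvature_field(mask, voxel_size=1.0, sigma_vx=2.0)
        assert abs(fld.area_weighted_mean) < 1.0  # mm^-1, vs 1/r scales of ~100

    def test_solid_cylinder_curvature_is_half_inverse_radius(self):
        r = 10
        y, x = np.ogrid[:64, :64]
        rod = np.broadcast_to((y - 32) ** 2 + (x - 32) ** 2 <= r * r, (64, 64, 64)).copy()
        fld = mean_curvature_field(rod, voxel_size=1.0, sigma_vx=2.0)
        assert fld.area_weighted_mean == pytest.approx(1.0 / (2 * r) * 1e3, rel=0.10)

    def test_sign_flips_under_complement(self):
        ball = digit_sphere((50, 50, 50), (25, 25, 25), 12)
        a = mean_curvature_field(ball, 1.0, 2.0).area_weighted_mean
        b = mean_curvature_field(~ball, 1.0, 2.0).area_weighted_mean
        assert a == pytest.approx(-b, rel=0.05)

    def test_principal_curvatures_ordered_and_average_to_mean(self):
        ball = digit_sphere((50, 50, 50), (25, 25, 25), 12)
        fld = mean_curvature_field(ball, 1.0, 2.0)
        assert np.all(fld.f_min <= fld.f_max + 1e-9)
        assert np.allclose((fld.f_min + fld.f_max) / 2.0, fld.mean)

    def test_mask_without_interface_raises(self):
        with pytest.raises(ValueError):
            mean_curvature_field(np.ones((10, 10, 10), dtype=bool), 1.0)

    def test_small_sigma_warns(self):
        ball = digit_sphere((30, 30, 30), (15, 15, 15), 8)
        with pytest.warns(UserWarning, match="sigma"):
            mean_curvature_field(ball, 1.0, sigma_vx=0.5)


class TestCurvatureDistribution:
    def test_bins_sum_to_100(self):
        ball = digit_sphere((50, 50, 50), (25, 25, 25), 12)
        dist = curvature_distribution(mean_curvature_field(ball, 1.0, 2.0))
        assert dist.values.sum() == pytest.approx(100.0)

    def test_sphere_histogram_unimodal_at_inverse_radius(self):
        ball = digit_sphere((60, 60, 60), (30, 30, 30), 15)
        fld = mean_curvature_field(ball, 1.0, 2.0)
        dist = curvature_distribution(fld, bin_width_mm=20.0)
        peak = np.argmax(dist.values)
        center = 0.5 * (dist.bin_edges[peak] + dist.bin_edges[peak + 1])
        assert center == pytest.approx(1000.0 / 15, abs=20.0)

    def test_slab_plus_sphere_masses_proportional_to_areas(self):
        mask = np.zeros((60, 60, 120), dtype=bool)
        mask[:, :, :30] = True                      # slab: flat interface 60x60
        mask |= digit_sphere((60, 60, 120), (30, 30, 80), 15)
        fld = mean_curvature_field(mask, 1.0, 2.0)
        dist = curvature_distribution(fld, bin_width_mm=20.0)
        flat_bin = np.digitize(0.0, dist.bin_edges) - 1
        sphere_bin = np.digitize(1000.0 / 15, dist.bin_edges) - 1
        flat_area = 60 * 60
        sphere_area = 4 * np.pi * 15**2
        expected_ratio = flat_area / sphere_area
        got_ratio = dist.values[flat_bin] / dist.values[sphere_bin]
        assert got_ratio == pytest.approx(expected_ratio, rel=0.35)
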