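"""Acoustic map construction and transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skullwave import media
from skullwave.media import (AcousticMap, CTVolume, LesionSpec,
                             SkullModelParams, SpeckleParams,
                             attenuation_from_density, clutter_reference,
                             ct_to_acoustic_map, generate_skull_slab,
                             generate_speckle_medium, homogenize_map,
                             insert_anechoic_lesion, insert_point_target,
                             isovelocity_transform, point_target_footprint,
                             uniform_map)


class TestAcousticMap:
    def test_invariants_enforced(self):
        good = uniform_map((8, 8), 1e-4)
        with pytest.raises(ValueError):
            AcousticMap(good.speed[:4], good.density, good.attenuation,
                        good.nonlinearity, dx=1e-4)
        with pytest.raises(ValueError):
            AcousticMap(-good.speed, good.density, good.attenuation,
                        good.nonlinearity, dx=1e-4)
        with pytest.raises(ValueError):
            AcousticMap(good.speed, good.density, good.attenuation,
                        good.nonlinearity, dx=0.0)

    def test_hdf5_roundtrip(self, tmp_path):
        m = uniform_map((6, 5), 5e-5)
        m.density[2, 3] = 1234.0
        m.save(tmp_path / "m.h5")
        back = AcousticMap.load(tmp_path / "m.h5")
        for name in ("speed", "density", "attenuation", "nonlinearity"):
            np.testing.assert_array_equal(getattr(m, name), getattr(back, name))
        assert back.dx == m.dx


class TestCTConversion:
    def _ct(self):
        hu = np.full((20, 20), -5.0)
        hu[5:15, 5:15] = np.linspace(700, 1700, 100).reshape(10, 10)
        return CTVolume(hu, spacing=1e-4)

    def test_linear_scaling_endpoints_and_midpoint(self):
        m = ct_to_acoustic_map(self._ct(), bone_threshold=300.0)
        hu = self._ct().hu
        bone = hu > 300
        lo, hi = hu[bone].min(), hu[bone].max()
        assert m.speed[hu == lo][0] == pytest.approx(1540.0)
        assert m.density[hu == lo][0] == pytest.approx(1000.0)
        assert m.speed[hu == hi][0] == pytest.approx(3000.0)
        assert m.density[hu == hi][0] == pytest.approx(1850.0)
        # voxel exactly midway maps onto the midpoint of both ranges
        mid = (lo + hi) / 2
        ct = self._ct()
        ct.hu[0, 0] = mid
        m2 = ct_to_acoustic_map(ct, bone_threshold=300.0)
        assert m2.speed[0, 0] == pytest.approx(2270.0)
        assert m2.density[0, 0] == pytest.approx(1425.0)

    def test_soft_tissue_background(self):
        m = ct_to_acoustic_map(self._ct(), bone_threshold=300.0)
        assert m.speed[0, 1] == 1540.0
        assert m.density[0, 1] == 1000.0
        assert m.attenuation[0, 1] == pytest.approx(0.3)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="threshold"):
            ct_to_acoustic_map(CTVolume(np.zeros((5, 5)), 1e-4),
                               bone_threshold=100.0)
        with pytest.raises(ValueError, match="constant|degenerate"):
            ct_to_acoustic_map(CTVolume(np.full((5, 5), 900.0), 1e-4),
                               bone_threshold=100.0)

    def test_air_water_calibration_line(self):
        ct = CTVolume(np.array([[-1000.0, 0.0]]), 1e-4,
                      air_ref=-1000.0, water_ref=0.0)
        rho = ct.calibrated_density()
        assert rho[0, 0] == pytest.approx(1.225)
        assert rho[0, 1] == pytest.approx(997.0)


class TestAttenuationFromDensity:
    def test_endpoints_and_sqrt_law(self):
        rho = np.array([1850.0, 1000.0, 1850.0 - 0.25 * 850.0])
        a = attenuation_from_density(rho, 2.8, 13.0)
        assert a[0] == pytest.approx(2.8)          # pure cortical
        assert a[1] == pytest.approx(13.0)         # pure marrow
        assert a[2] == pytest.approx(2.8 + 0.5 * (13.0 - 2.8))  # sqrt(0.25)

    def test_out_of_range_density_named_in_error(self):
        with pytest.raises(ValueError, match="999"):
            attenuation_from_density(np.array([999.0]), 2.8, 13.0)

    @given(st.lists(st.floats(1000.0, 1850.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_density(self, rhos):
        rho = np.sort(np.asarray(rhos))
        a = attenuation_from_density(rho, 2.8, 13.0)
        assert np.all(np.diff(a) <= 1e-12)


class TestSkullSlab:
    def test_zero_porosity_gives_cortical_slab(self):
        p = SkullModelParams(porosity_amplitude=0.0, surface_roughness=0.0,
                             seed=1)
        m = generate_skull_slab(p, (120, 60), 1e-4)
        bone = m.speed > 1540.0
        assert bone.any()
        assert np.allclose(m.speed[bone], 3000.0)
        assert np.allclose(m.density[bone], 1850.0)

    def test_temporal_window_variant_is_all_cortical(self):
        p = SkullModelParams(outer_cortical=3e-3, diploe_thickness=0.0,
                             inner_cortical=0.0, surface_roughness=0.0, seed=1)
        m = generate_skull_slab(p, (120, 60), 1e-4)
        bone = m.speed > 1540.0
        assert np.allclose(m.speed[bone], 3000.0)

    def test_deterministic_given_seed(self):
        p = SkullModelParams(seed=9)
        a = generate_skull_slab(p, (150, 60), 1e-4)
        b = generate_skull_slab(p, (150, 60), 1e-4)
        np.testing.assert_array_equal(a.density, b.density)
        c = generate_skull_slab(SkullModelParams(seed=10), (150, 60), 1e-4)
        assert not np.array_equal(a.density, c.density)

    def test_layers_exceeding_extent_raise(self):
        p = SkullModelParams(standoff=5e-3, diploe_thickness=10e-3)
        with pytest.raises(ValueError, match="exceed"):
            generate_skull_slab(p, (50, 40), 1e-4)

    def test_trabecular_mode_is_binary(self):
        p = SkullModelParams(microstructure="trabecular",
                             porosity_amplitude=1.0, seed=2)
        m = generate_skull_slab(p, (150, 80), 1e-4)
        diploe = (m.density > 1000.0) & (m.density < 1850.0)
        assert not diploe.any()  # only marrow or cortical values


class TestSpeckle:
    def test_zero_variation_is_homogeneous(self):
        p = SpeckleParams(fractional_variation=0.0, seed=0)
        m = generate_speckle_medium(p, (100, 100), 5e-5, f0=2.5e6)
        assert np.allclose(m.density, 1000.0)

    def test_scatterer_count_follows_sampling_law(self):
        p = SpeckleParams(seed=4)
        dx = 5e-5
        shape = (400, 400)
        m = generate_speckle_medium(p, shape, dx, f0=2.5e6)
        n = int((m.density != 1000.0).sum())
        lam = 1540.0 / 2.5e6
        mean = 15.0 * (shape[0] * dx) * (shape[1] * dx) / lam**2
        assert abs(n - mean) < 3.0 * np.sqrt(mean)  # Poisson sampling law

    def test_mean_density_preserved(self):
        m = generate_speckle_medium(SpeckleParams(seed=4), (400, 400), 5e-5,
                                    f0=2.5e6)
        assert abs(m.density.mean() - 1000.0) / 1000.0 < 1e-3

    def test_unresolved_scatterers_raise(self):
        with pytest.raises(ValueError, match="resolve"):
            generate_speckle_medium(SpeckleParams(), (50, 50), 1e-3, f0=2.5e6)


class TestLesion:
    def _speckled(self):
        return generate_speckle_medium(SpeckleParams(seed=4), (400, 300),
                                       5e-5, f0=2.5e6)

    def test_interior_cleared_and_nonattenuating(self):
        m = self._speckled()
        spec = LesionSpec(center=(0.0, 10e-3), diameter=6e-3)
        out = insert_anechoic_lesion(m, spec)
        zz = out.z_coords[:, None]
        xx = out.x_coords[None, :]
        inside = (zz - 10e-3) ** 2 + xx**2 <= (3e-3) ** 2
        assert np.all(out.density[inside] == 1000.0)
        assert np.all(out.attenuation[inside] == 0.0)
        outside_changed = (out.density != m.density) & ~inside
        assert not outside_changed.any()

    def test_zero_diameter_is_identity(self):
        m = self._speckled()
        out = insert_anechoic_lesion(m, LesionSpec(center=(0.0, 10e-3),
                                                   diameter=0.0))
        np.testing.assert_array_equal(out.density, m.density)

    def test_disc_outside_map_raises(self):
        with pytest.raises(ValueError, match="fit"):
            insert_anechoic_lesion(self._speckled(),
                                   LesionSpec(center=(0.0, 1e-3)))


class TestPointTarget:
    def test_zero_brightness_is_identity(self):
        m = uniform_map((100, 80), 1e-4)
        out = insert_point_target(m, depth=5e-3, brightness_scale=0.0)
        np.testing.assert_array_equal(out.density, m.density)

    def test_contrast_proportional_to_brightness(self):
        m = uniform_map((100, 80), 1e-4)
        a = insert_point_target(m, depth=5e-3, brightness_scale=1.0)
        b = insert_point_target(m, depth=5e-3, brightness_scale=0.25)
        da = (a.density - m.density).max()
        db = (b.density - m.density).max()
        assert da / db == pytest.approx(4.0)

    def test_two_targets_coexist(self):
        m = uniform_map((200, 80), 1e-4)
        out = insert_point_target(m, depth=5e-3)
        out = insert_point_target(out, depth=15e-3)
        fp1 = point_target_footprint(m, 5e-3)
        fp2 = point_target_footprint(m, 15e-3)
        assert (out.density[fp1] > 1000).all()
        assert (out.density[fp2] > 1000).all()
        assert np.array_equal(out.density[~(fp1 | fp2)],
                              m.density[~(fp1 | fp2)])

    def test_position_outside_map_raises(self):
        with pytest.raises(ValueError, match="outside"):
            insert_point_target(uniform_map((50, 50), 1e-4), depth=1.0)


class TestClutterReference:
    def test_round_trip_with_background(self):
        m = generate_speckle_medium(SpeckleParams(seed=4), (200, 100), 5e-5,
                                    f0=2.5e6)
        withtgt = insert_point_target(m, depth=5e-3)
        fp = point_target_footprint(m, 5e-3)
        back = clutter_reference(withtgt, fp, background=m)
        np.testing.assert_array_equal(back.density, m.density)

    def test_only_footprint_pixels_differ(self):
        m = uniform_map((100, 80), 1e-4)
        withtgt = insert_point_target(m, depth=5e-3)
        fp = point_target_footprint(m, 5e-3)
        out = clutter_reference(withtgt, fp)
        diff = out.density != withtgt.density
        assert diff.any()
        assert not (diff & ~fp).any()
        np.testing.assert_array_equal(out.density, m.density)

    def test_empty_footprint_raises(self):
        m = uniform_map((50, 50), 1e-4)
        with pytest.raises(ValueError, match="empty"):
            clutter_reference(m, np.zeros(m.shape, dtype=bool))


class TestHomogenize:
    def _structured(self):
        rng = np.random.default_rng(0)
        m = uniform_map((160, 120), 1e-4)
        m.density += 200.0 * rng.random(m.shape)
        m.speed += 300.0 * rng.random(m.shape)
        return m

    def test_identity_at_native_resolution(self):
        m = self._structured()
        out = homogenize_map(m, m.dx)
        np.testing.assert_array_equal(out.density, m.density)

    @pytest.mark.parametrize("method", ["mean", "subsample"])
    def test_idempotent(self, method):
        m = self._structured()
        once = homogenize_map(m, 8e-4, method=method)
        twice = homogenize_map(once, 8e-4, method=method)
        assert np.max(np.abs(twice.density - once.density)
                      / once.density) < 1e-6

    def test_mean_preserved(self):
        m = self._structured()
        out = homogenize_map(m, 8e-4)
        assert abs(out.density.mean() - m.density.mean()) / m.density.mean() \
            < 5e-3

    def test_fine_features_suppressed(self):
        m = self._structured()
        out = homogenize_map(m, 8e-4)
        # spatial spectrum above the coarse cut must collapse
        f_fine = np.abs(np.fft.rfft(m.density - m.density.mean(), axis=0))
        f_coar = np.abs(np.fft.rfft(out.density - out.density.mean(), axis=0))
        hi = slice(40, None)  # wavelengths shorter than ~2 coarse cells
        assert f_coar[hi].sum() < 0.2 * f_fine[hi].sum()

    def test_too_fine_resolution_raises(self):
        with pytest.raises(ValueError):
            homogenize_map(self._structured(), 5e-5)


class TestIsovelocity:
    def test_impedance_preserved_everywhere(self):
        m = generate_skull_slab(SkullModelParams(seed=3), (200, 100), 1e-4)
        out = isovelocity_transform(m)
        rel = np.abs(out.impedance - m.impedance) / m.impedance
        assert rel.max() < 1e-12
        assert np.all(out.speed == 1540.0)

    def test_matched_homogeneous_map_unchanged(self):
        m = uniform_map((50, 50), 1e-4)
        out = isovelocity_transform(m, 1540.0)
        np.testing.assert_allclose(out.density, m.density)

    def test_density_rescaling_oracle(self):
        m = uniform_map((4, 4), 1e-4, speed=3000.0, density=1850.0)
        out = isovelocity_transform(m, 1540.0)
        assert out.density[0, 0] == pytest.approx(1850.0 * 3000.0 / 1540.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_impedance_preservation_is_universal(self, seed):
        rng = np.random.default_rng(seed)
        m = uniform_map((20, 20), 1e-4)
        m.speed = 1540.0 + 1500.0 * rng.random(m.shape)
        m.density = 1000.0 + 900.0 * rng.random(m.shape)
        out = isovelocity_transform(m)
        rel = np.abs(out.impedance - m.impedance) / m.impedance
        assert rel.max() < 1e-12
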