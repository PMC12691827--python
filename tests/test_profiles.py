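import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvnperm import (
    LineProfile,
    LumenBounds,
    PermeabilityProfile,
    aggregate_profiles,
    auto_place_scanlines,
    average_projection,
    detect_lumen_bounds,
    extract_line_profile,
    fit_linear,
    max_projection,
    mean_permeability,
    normalize_tracer_profile,
    render_scene,
    slope_fold_change,
    vessel_diameter,
)
from .conftest import cylinder_scene

FWHM_FACTOR = 2 * np.sqrt(2 * np.log(2))


def gaussian_profile(sigma=5.0, half_span=50.0, spacing=0.5, baseline=0.0, amp=1.0):
    pos = np.arange(0, 2 * half_span + spacing / 2, spacing)
    ves = baseline + amp * np.exp(-((pos - half_span) ** 2) / (2 * sigma**2))
    return LineProfile(positions=pos, vessel_values=ves, tracer_values=np.ones_like(pos))


class TestExtractLineProfile:
    def test_constant_image(self):
        img = np.full((10, 10), 42.0)
        prof = extract_line_profile(img, img, (1.0, 1.0), (1.0, 5.0), (9.0, 5.0), 0.5)
        np.testing.assert_allclose(prof.vessel_values, 42.0)
        np.testing.assert_allclose(prof.tracer_values, 42.0)

    def test_axis_aligned_scan_reads_column_indices(self):
        img = np.tile(np.arange(8.0), (8, 1))  # column x has value x
        prof = extract_line_profile(img, img, (1.0, 1.0), (0.5, 4.0), (7.5, 4.0), 1.0)
        np.testing.assert_allclose(prof.vessel_values, np.arange(8.0))

    def test_diagonal_scan_on_linear_ramp_matches_closed_form(self):
        # f(x, y) = 2x + 3y is preserved exactly by bilinear interpolation
        y, x = np.mgrid[0:12, 0:12]
        img = 2.0 * (x + 0.5) + 3.0 * (y + 0.5)  # value at pixel centre (µm coords)
        p0, p1 = (2.0, 3.0), (9.0, 10.0)
        prof = extract_line_profile(img, img, (1.0, 1.0), p0, p1, 0.7)
        length = np.hypot(p1[0] - p0[0], p1[1] - p0[1])
        t = prof.positions / length
        expected = 2.0 * (p0[0] + t * (p1[0] - p0[0])) + 3.0 * (p0[1] + t * (p1[1] - p0[1]))
        np.testing.assert_allclose(prof.vessel_values, expected, atol=1e-9)

    def test_endpoint_outside_image_rejected(self):
        img = np.ones((5, 5))
        with pytest.raises(ValueError, match="outside"):
            extract_line_profile(img, img, (1.0, 1.0), (0.0, 0.0), (10.0, 0.0), 0.5)

    def test_zero_length_segment_rejected(self):
        img = np.ones((5, 5))
        with pytest.raises(ValueError, match="zero-length"):
            extract_line_profile(img, img, (1.0, 1.0), (2.0, 2.0), (2.0, 2.0), 0.5)


class TestDetectLumenBounds:
    def test_rectangular_pulse(self):
        pos = np.arange(0.0, 40.0, 0.1)
        ves = np.where((pos >= 10) & (pos <= 30), 100.0, 0.0)
        prof = LineProfile(positions=pos, vessel_values=ves, tracer_values=np.zeros_like(pos))
        b = detect_lumen_bounds(prof)
        assert b.left == pytest.approx(10.0, abs=0.1)
        assert b.right == pytest.approx(30.0, abs=0.1)

    def test_gaussian_fwhm(self):
        b = detect_lumen_bounds(gaussian_profile(sigma=5.0))
        assert vessel_diameter(b) == pytest.approx(FWHM_FACTOR * 5.0, rel=0.005)

    def test_baseline_offset_does_not_change_width(self):
        b = detect_lumen_bounds(gaussian_profile(sigma=5.0, baseline=200.0, amp=100.0))
        assert vessel_diameter(b) == pytest.approx(FWHM_FACTOR * 5.0, rel=0.005)

    def test_mirroring_swaps_bounds(self):
        prof = gaussian_profile(sigma=4.0)
        # build an asymmetric profile so the mirror test is non-trivial
        ves = prof.vessel_values + 0.2 * np.exp(-((prof.positions - 70) ** 2) / 18.0)
        prof = LineProfile(prof.positions, ves, prof.tracer_values)
        mirrored = LineProfile(prof.positions, ves[::-1], prof.tracer_values)
        b = detect_lumen_bounds(prof)
        bm = detect_lumen_bounds(mirrored)
        span = prof.positions[-1]
        assert bm.left == pytest.approx(span - b.right, abs=1e-9)
        assert bm.right == pytest.approx(span - b.left, abs=1e-9)
        assert vessel_diameter(bm) == pytest.approx(vessel_diameter(b))

    def test_monotone_profile_has_no_enclosed_lumen(self):
        pos = np.arange(0.0, 20.0, 0.5)
        prof = LineProfile(pos, np.linspace(0, 100, pos.size), np.zeros_like(pos))
        with pytest.raises(ValueError, match="no enclosed lumen"):
            detect_lumen_bounds(prof)

    def test_blurred_cylinder_diameter_within_one_voxel(self):
        for radius in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0):
            scene = cylinder_scene(radius=radius, shape=(32, 128, 128), psf_sigma=2.0)
            stack, _ = render_scene(scene)
            vmax, ps = max_projection(stack.vessel)
            tavg, _ = average_projection(stack.tracer)
            yc = 128.0
            prof = extract_line_profile(vmax, tavg, ps, (128.0, yc - 60), (128.0, yc + 60), 0.5)
            d = vessel_diameter(detect_lumen_bounds(prof))
            assert abs(d - 2 * radius) <= 2.0, f"radius {radius}: got {d}"


class TestNormalize:
    @staticmethod
    def tube_profile(luminal=200.0, outside=125.0, left=10.0, right=30.0):
        pos = np.arange(0.0, 80.0, 0.5)
        tracer = np.where((pos > left) & (pos < right), luminal, outside)
        vessel = np.where((pos > left) & (pos < right), 1000.0, 0.0)
        return LineProfile(pos, vessel, tracer)

    def test_tracer_equal_to_luminal_gives_100pct(self):
        prof = self.tube_profile(luminal=200.0, outside=200.0)
        bounds = LumenBounds(left=10.0, right=30.0, level=500.0, level_fraction=0.5)
        pp = normalize_tracer_profile(prof, bounds, background=0.0, max_distance=40.0)
        np.testing.assert_allclose(pp.values, 100.0)

    def test_forced_arithmetic(self):
        prof = self.tube_profile(luminal=200.0, outside=125.0)
        bounds = LumenBounds(left=10.0, right=30.0, level=500.0, level_fraction=0.5)
        pp = normalize_tracer_profile(prof, bounds, background=50.0, max_distance=40.0)
        # (125 − 50) / (200 − 50) = 50 %
        np.testing.assert_allclose(pp.values[1:], 50.0)

    def test_luminal_below_background_rejected(self):
        prof = self.tube_profile(luminal=40.0, outside=30.0)
        bounds = LumenBounds(left=10.0, right=30.0, level=500.0, level_fraction=0.5)
        with pytest.raises(ValueError, match="background"):
            normalize_tracer_profile(prof, bounds, background=50.0)

    @given(scale=st.floats(0.01, 1000.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        prof = self.tube_profile(luminal=200.0, outside=125.0)
        scaled = LineProfile(prof.positions, prof.vessel_values, prof.tracer_values * scale)
        bounds = LumenBounds(left=10.0, right=30.0, level=500.0, level_fraction=0.5)
        base = normalize_tracer_profile(prof, bounds, background=50.0, max_distance=40.0)
        other = normalize_tracer_profile(scaled, bounds, background=50.0 * scale, max_distance=40.0)
        np.testing.assert_allclose(other.values, base.values, rtol=1e-9)

    def test_idempotence_on_normalized_profile(self):
        prof = self.tube_profile(luminal=100.0, outside=60.0)
        bounds = LumenBounds(left=10.0, right=30.0, level=50.0, level_fraction=0.5)
        once = normalize_tracer_profile(prof, bounds, background=0.0, max_distance=40.0)
        assert once.luminal_reference == pytest.approx(100.0)
        np.testing.assert_allclose(once.values[1:], 60.0)  # already in % of luminal

    def test_noiseless_generator_profile_matches_analytic(self):
        from mvnperm import analytic_profile

        scene = cylinder_scene(radius=15.0, shape=(16, 128, 256))
        stack, _ = render_scene(scene)
        vmax, ps = max_projection(stack.vessel)
        tavg, _ = average_projection(stack.tracer)
        yc = 128.0
        prof = extract_line_profile(vmax, tavg, ps, (256.0, 8.0), (256.0, 252.0), 1.0)
        bounds = detect_lumen_bounds(prof)
        pp = normalize_tracer_profile(prof, bounds, background=0.0, max_distance=100.0,
                                      core_fraction=0.5)
        expected = analytic_profile(scene, pp.distances)
        # away from the blurred border zone the profile matches the closed form
        away = pp.distances > 10.0
        np.testing.assert_allclose(pp.values[away], expected[away], rtol=0.03)


class TestAggregate:
    @staticmethod
    def linear_pp(intercept, slope, dmax=100.0, step=1.0):
        d = np.arange(0.0, dmax + step / 2, step)
        return PermeabilityProfile(d, intercept + slope * d, 100.0, 0.0)

    def test_identical_profiles_aggregate_to_themselves(self):
        p = self.linear_pp(100.0, -0.2)
        single = aggregate_profiles([p], bin_width=5.0)
        agg = aggregate_profiles([p, p], bin_width=5.0)
        np.testing.assert_allclose(agg.values, single.values, atol=1e-12)
        np.testing.assert_allclose(agg.dispersion, 0.0, atol=1e-12)
        assert fit_linear(agg).slope == pytest.approx(-0.2, rel=0.02)

    def test_constant_profiles_average(self):
        a = self.linear_pp(100.0, 0.0)
        b = self.linear_pp(80.0, 0.0)
        agg = aggregate_profiles([a, b], bin_width=5.0)
        np.testing.assert_allclose(agg.values, 90.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no profiles"):
            aggregate_profiles([], bin_width=5.0)


class TestFits:
    def test_exact_on_collinear_points(self):
        pp = PermeabilityProfile(np.array([0.0, 50.0, 100.0]), np.array([100.0, 90.0, 80.0]), 100.0, 0.0)
        fit = fit_linear(pp)
        assert fit.slope == pytest.approx(-0.2)
        assert fit.intercept == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_profile_has_zero_slope(self):
        pp = PermeabilityProfile(np.arange(5.0), np.full(5, 87.0), 100.0, 0.0)
        assert fit_linear(pp).slope == pytest.approx(0.0)

    def test_degenerate_distances_rejected(self):
        pp = PermeabilityProfile(np.array([0.0]), np.array([100.0]), 100.0, 0.0)
        with pytest.raises(ValueError, match="distinct"):
            fit_linear(pp)

    def test_fold_change_forced_arithmetic(self):
        from mvnperm import LinearFit

        a = LinearFit(slope=-0.36, intercept=90.0, r_squared=1.0, n_points=10)
        b = LinearFit(slope=-0.10, intercept=90.0, r_squared=1.0, n_points=10)
        assert slope_fold_change(a, b) == pytest.approx(3.6)
        assert slope_fold_change(a, a) == pytest.approx(1.0)

    def test_fold_change_sign_mismatch(self):
        from mvnperm import LinearFit

        neg = LinearFit(slope=-0.1, intercept=90.0, r_squared=1.0, n_points=5)
        pos = LinearFit(slope=0.1, intercept=90.0, r_squared=1.0, n_points=5)
        with pytest.raises(ValueError, match="sign"):
            slope_fold_change(neg, pos)

    def test_fold_change_from_generator_slopes(self):
        # two noiseless linear profiles with b = −0.004 and −0.001 → ratio 4
        a = fit_linear(TestAggregate.linear_pp(90.0, -0.4))
        b = fit_linear(TestAggregate.linear_pp(90.0, -0.1))
        assert slope_fold_change(a, b) == pytest.approx(4.0)

    def test_mean_permeability_linear_and_constant(self):
        assert mean_permeability(TestAggregate.linear_pp(100.0, -0.2)) == pytest.approx(90.0)
        assert mean_permeability(TestAggregate.linear_pp(87.0, 0.0)) == pytest.approx(87.0)


class TestAutoScanlines:
    def test_horizontal_tube_gives_vertical_scans(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:35, :] = True
        lines = auto_place_scanlines(mask, (1.0, 1.0), n=5, min_separation=5.0,
                                     scan_half_length=20.0, seed=0)
        assert lines
        for (x0, y0), (x1, y1) in lines:
            dx, dy = abs(x1 - x0), abs(y1 - y0)
            assert dy > 10 * max(dx, 1e-9)  # vertical within ~5° of perpendicular

    def test_seed_determinism(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:26, :] = True
        a = auto_place_scanlines(mask, (1.0, 1.0), 5, 5.0, 20.0, seed=7)
        b = auto_place_scanlines(mask, (1.0, 1.0), 5, 5.0, 20.0, seed=7)
        c = auto_place_scanlines(mask, (1.0, 1.0), 5, 5.0, 20.0, seed=8)
        assert a == b
        assert a != c

    def test_most_scans_yield_valid_bounds(self):
        scene = cylinder_scene(radius=15.0, shape=(16, 128, 256), noise=(50.0, 1.0), seed=3)
        stack, gt = render_scene(scene)
        vmax, ps = max_projection(stack.vessel)
        tavg, _ = average_projection(stack.tracer)
        lines = auto_place_scanlines(gt.mask.any(axis=0), ps, n=20, min_separation=8.0,
                                     scan_half_length=125.0, seed=1)
        ok = 0
        for p0, p1 in lines:
            try:
                prof = extract_line_profile(vmax, tavg, ps, p0, p1, 1.0)
                detect_lumen_bounds(prof)
                ok += 1
            except ValueError:
                pass
        assert ok >= 0.9 * len(lines)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auto_place_scanlines(np.zeros((8, 8), bool), (1.0, 1.0), 3, 1.0, 5.0, seed=0)
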