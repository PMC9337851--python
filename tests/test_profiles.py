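"""Gaussian profile fitting, peak-aligned averaging, and vesicle contour
alignment/measurement."""

import numpy as np
import pytest

from mitopits.profiles import (FWHM_FACTOR, ContourPair, LineProfile,
                               align_and_average, align_contour_major_axis,
                               fit_gaussian, measure_vesicle)
from mitopits.synthetic import ContourSpec, ProfileSpec, generate_profile_set


def gauss(x, a, c, s, b):
    return b + a * np.exp(-((x - c) ** 2) / (2 * s**2))


def ellipse(a, b, phi=0.0, n=100, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return pts @ rot.T + np.asarray(center)


class TestFitGaussian:
    def test_exact_recovery_of_noiseless_gaussian(self):
        x = np.linspace(-400, 500, 91)
        fit = fit_gaussian(x, gauss(x, 100.0, 40.0, 90.0, 10.0))
        assert fit.converged
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.center_nm == pytest.approx(40.0, abs=1e-4)
        assert fit.sigma_nm == pytest.approx(90.0, rel=1e-6)
        assert fit.baseline == pytest.approx(10.0, rel=1e-6)

    def test_mirrored_trace_same_center(self):
        x = np.linspace(-450, 450, 91)
        y = gauss(x, 80.0, 0.0, 100.0, 5.0) + 0.3 * np.sin(x / 37.0) ** 2
        y_sym = 0.5 * (y + y[::-1])  # symmetric about 0 by construction
        fit = fit_gaussian(x, y_sym)
        assert fit.center_nm == pytest.approx(0.0, abs=1e-6)

    def test_flat_trace_not_converged(self):
        x = np.linspace(0, 100, 11)
        fit = fit_gaussian(x, np.full(11, 7.0))
        assert not fit.converged
        assert fit.baseline == pytest.approx(7.0)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.arange(4.0), np.arange(4.0))

    def test_noisy_center_within_3se(self):
        x = np.linspace(-450, 450, 91)
        rng = np.random.default_rng(2)
        centers = []
        for _ in range(100):
            y = gauss(x, 100.0, 40.0, 90.0, 10.0) + rng.normal(0, 5.0, x.size)
            fit = fit_gaussian(x, y)
            assert fit.converged
            centers.append(fit.center_nm)
        se = np.std(centers, ddof=1) / 10.0
        assert abs(np.mean(centers) - 40.0) <= 3 * se


class TestAlignAndAverage:
    def test_planted_offsets_recovered_exactly(self):
        profiles = generate_profile_set(
            ProfileSpec(seed=0, n_profiles=10, noise_sd=0.0))
        out = align_and_average(profiles, "hook")
        assert np.allclose(out.offsets_nm["hook"], 0.0, atol=1e-6)
        assert np.allclose(out.offsets_nm["anchor"], -80.0, atol=1e-4)
        assert np.allclose(out.offsets_nm["matrix"], -180.0, atol=1e-4)
        assert out.n_used == 10 and out.n_excluded == 0

    def test_single_profile_mean_is_shifted_trace_sd_zero(self):
        profiles = generate_profile_set(
            ProfileSpec(seed=1, n_profiles=1, noise_sd=0.0,
                        center_jitter_sd_nm=0.0))
        out = align_and_average(profiles, "hook")
        assert np.allclose(out.sd["hook"], 0.0)
        expected = np.interp(out.grid_nm, profiles[0].distance_nm,
                             profiles[0].intensities["anchor"])
        assert np.allclose(out.mean["anchor"], expected)

    def test_invariant_under_constant_distance_shift(self):
        profiles = generate_profile_set(
            ProfileSpec(seed=3, n_profiles=5, noise_sd=2.0))
        shifted = [LineProfile(distance_nm=p.distance_nm + 137.0,
                               intensities=p.intensities)
                   for p in profiles]
        a = align_and_average(profiles, "hook")
        b = align_and_average(shifted, "hook")
        np.testing.assert_allclose(a.grid_nm, b.grid_nm, atol=1e-9)
        for ch in ("hook", "anchor", "matrix"):
            np.testing.assert_allclose(a.mean[ch], b.mean[ch], atol=1e-6)
            np.testing.assert_allclose(a.offsets_nm[ch], b.offsets_nm[ch],
                                       atol=1e-6)

    def test_noisy_offsets_within_3se(self):
        profiles = generate_profile_set(
            ProfileSpec(seed=5, n_profiles=50, noise_sd=10.0))
        out = align_and_average(profiles, "hook")
        for ch, truth in (("anchor", -80.0), ("matrix", -180.0)):
            offs = out.offsets_nm[ch]
            se = np.std(offs, ddof=1) / np.sqrt(len(offs))
            assert abs(np.mean(offs) - truth) <= 3 * se

    def test_fwhm_identity(self):
        profiles = generate_profile_set(
            ProfileSpec(seed=0, n_profiles=3, noise_sd=0.0))
        out = align_and_average(profiles, "hook")
        for ch in ("hook", "anchor", "matrix"):
            np.testing.assert_allclose(out.fwhm_nm[ch],
                                       FWHM_FACTOR * out.sigma_nm[ch])

    def test_nonconverging_reference_excluded_and_counted(self):
        profiles = generate_profile_set(
            ProfileSpec(seed=0, n_profiles=4, noise_sd=0.0))
        flat = LineProfile(
            distance_nm=profiles[0].distance_nm.copy(),
            intensities={ch: np.full_like(v, 3.0)
                         for ch, v in profiles[0].intensities.items()})
        with pytest.warns(UserWarning):
            out = align_and_average(profiles + [flat], "hook")
        assert out.n_used == 4 and out.n_excluded == 1
        assert out.n_used + out.n_excluded == 5


class TestContourAlignment:
    def test_tilted_ellipse_max_y_is_semiminor(self):
        pts = ellipse(70.0, 50.0, phi=np.pi / 4)
        aligned = align_contour_major_axis(pts)
        assert np.max(np.abs(aligned[:, 1])) == pytest.approx(50.0, abs=1e-6)

    def test_circle_degenerate_radius_preserved(self):
        pts = ellipse(60.0, 60.0, phi=0.3)
        aligned = align_contour_major_axis(pts)
        # rotation is arbitrary for a circle; the sampled vertices then miss
        # the extreme by up to r*(pi/n)^2/2
        assert np.max(np.abs(aligned[:, 1])) == pytest.approx(60.0, abs=0.01)

    def test_idempotent(self):
        pts = ellipse(70.0, 50.0, phi=1.1, center=(300.0, -200.0))
        once = align_contour_major_axis(pts)
        twice = align_contour_major_axis(once)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_collinear_points_raise(self):
        line = np.column_stack([np.linspace(0, 10, 12), np.zeros(12)])
        with pytest.raises(ValueError):
            align_contour_major_axis(line)


class TestMeasureVesicle:
    def test_concentric_circles_exact(self):
        pair = ContourPair(outer=ellipse(60.0, 60.0), inner=ellipse(50.0, 50.0))
        m = measure_vesicle(pair)
        assert m.outer_diameter_nm == pytest.approx(120.0, abs=1e-9)
        assert m.intermembrane_distance_nm == pytest.approx(10.0, abs=0.02)

    def test_offset_ellipse(self):
        spec = ContourSpec(seed=0, axis_ratio=1.4,
                           outer_diameter_mean_nm=120.0,
                           intermembrane_distance_mean_nm=10.0,
                           orientation=0.6, n_vesicles=1)
        from mitopits.synthetic import generate_contour_pairs
        m = measure_vesicle(generate_contour_pairs(spec)[0])
        assert m.outer_diameter_nm == pytest.approx(120.0, abs=0.5)
        assert m.intermembrane_distance_nm == pytest.approx(10.0, abs=0.1)

    def test_rigid_motion_invariance(self):
        outer, inner = ellipse(70.0, 50.0, phi=0.2), ellipse(60.0, 40.0, phi=0.2)
        m0 = measure_vesicle(ContourPair(outer=outer, inner=inner))
        phi = 0.8
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        shift = np.array([123.0, -456.0])
        m1 = measure_vesicle(ContourPair(outer=outer @ rot.T + shift,
                                         inner=inner @ rot.T + shift))
        assert m1.outer_diameter_nm == pytest.approx(m0.outer_diameter_nm,
                                                     abs=1e-9)
        assert m1.intermembrane_distance_nm == pytest.approx(
            m0.intermembrane_distance_nm, abs=1e-9)

    def test_crossing_contours_raise(self):
        outer = ellipse(60.0, 60.0)
        inner = ellipse(50.0, 50.0, center=(30.0, 0.0))  # pokes outside
        with pytest.raises(ValueError):
            measure_vesicle(ContourPair(outer=outer, inner=inner))
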