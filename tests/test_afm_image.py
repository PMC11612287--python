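import numpy as np
import pytest

from envmech.afm_image import (
    HeightMap,
    Profile,
    align_rows,
    extract_profile,
    feature_protrusion,
    flatten_base,
    plane_level,
    rms_roughness,
    smooth,
)
from envmech.synthetic_scene import SceneTruth, render_height_image, scene_from_preset


def _map(values, px=2.0, **kw):
    return HeightMap(values=np.asarray(values, dtype=float), pixel_size=px, **kw)


class TestPlaneLevel:
    def test_exact_plane_removal(self):
        yy, xx = np.mgrid[0:64, 0:64]
        m = _map(0.01 * xx + 0.02 * yy + 5.0)
        out = plane_level(m, mask_high=False)
        assert np.abs(out.values).max() < 1e-9

    def test_noisy_plane_residual_matches_lstsq_oracle(self, rng):
        yy, xx = np.mgrid[0:64, 0:64]
        noise = rng.normal(0, 1.0, (64, 64))
        m = _map(0.01 * xx + 0.02 * yy + noise)
        out = plane_level(m, mask_high=False)
        # oracle: direct least-squares plane residual
        A = np.column_stack([np.ones(64 * 64), xx.ravel(), yy.ravel()])
        coef, *_ = np.linalg.lstsq(A, m.values.ravel(), rcond=None)
        oracle = m.values.ravel() - A @ coef
        assert np.allclose(out.values.ravel(), oracle, atol=1e-9)
        assert out.values.std() == pytest.approx(1.0, rel=0.05)

    def test_constant_image_zeroed(self):
        out = plane_level(_map(np.full((16, 16), 7.0)))
        assert np.abs(out.values).max() < 1e-9

    def test_high_pixels_excluded_from_fit(self):
        values = np.zeros((32, 32))
        values[10:20, 10:20] = 100.0  # protruding feature
        out = plane_level(_map(values), mask_high=True)
        bg = out.values[values == 0]
        assert np.abs(bg).max() < 1e-9
        assert out.values[15, 15] == pytest.approx(100.0)

    def test_too_few_pixels_error(self):
        m = _map(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            plane_level(m, mask_high=False)

    def test_idempotent(self, rng):
        m = _map(rng.normal(0, 1, (48, 48)))
        once = plane_level(m, mask_high=False)
        twice = plane_level(once, mask_high=False)
        assert np.abs(twice.values - once.values).max() < 1e-9


class TestAlignRows:
    def test_row_offsets_removed_order0(self, rng):
        offsets = rng.normal(0, 5, 32)
        m = _map(np.tile(offsets[:, None], (1, 64)))
        out = align_rows(m, order=0)
        assert np.abs(out.values).max() < 1e-9

    def test_quadratic_bow_residual_matches_polyfit_oracle(self, rng):
        x = np.linspace(-1, 1, 128)
        noise = rng.normal(0, 0.5, (32, 128))
        bow = 10.0 * x**2
        m = _map(bow[None, :] + noise)
        out = align_rows(m, order=2)
        assert out.values.std() == pytest.approx(0.5, rel=0.1)
        # oracle: per-row polynomial residual computed independently
        i = 7
        coef = np.polyfit(x, m.values[i], 2)
        oracle = m.values[i] - np.polyval(coef, x)
        assert np.allclose(out.values[i], oracle, atol=1e-8)

    def test_zero_image_unchanged(self):
        out = align_rows(_map(np.zeros((8, 8))))
        assert np.abs(out.values).max() == 0.0

    def test_starved_row_left_unchanged(self):
        values = np.arange(64, dtype=float).reshape(8, 8)
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, :6] = True  # leaves 2 pixels, fewer than order+1
        out = align_rows(_map(values, mask=mask), order=2)
        assert np.array_equal(out.values[3], values[3])

    def test_idempotent(self, rng):
        m = _map(rng.normal(0, 1, (16, 64)))
        once = align_rows(m)
        twice = align_rows(once)
        assert np.abs(twice.values - once.values).max() < 1e-9


class TestFlattenBase:
    def test_cell_on_substrate(self, rng):
        # oracle: the plane fitted on the known substrate footprint only
        yy, xx = np.mgrid[0:50, 0:50]
        substrate = 0.02 * xx - 0.01 * yy + rng.normal(0, 0.03, (50, 50))
        values = substrate.copy()
        cell = np.zeros((50, 50), dtype=bool)
        cell[15:35, 15:35] = True  # ~16% of pixels
        values[cell] += 100.0
        out = flatten_base(_map(values))
        assert abs(np.median(out.values[~cell])) < 0.1
        assert out.values[cell].mean() == pytest.approx(100.0, abs=0.5)

    def test_flat_image_unchanged(self):
        out = flatten_base(_map(np.zeros((16, 16))))
        assert np.abs(out.values).max() < 1e-12

    def test_all_cell_reduces_to_plane_level(self):
        yy, xx = np.mgrid[0:32, 0:32]
        m = _map(0.05 * xx + 3.0)
        out = flatten_base(m)
        ref = plane_level(m, mask_high=False)
        assert np.allclose(out.values, ref.values, atol=1e-9)

    def test_roughly_idempotent(self, rng):
        m = _map(rng.normal(0, 1, (64, 64)))
        once = flatten_base(m)
        twice = flatten_base(once)
        assert twice.values.std() == pytest.approx(once.values.std(), rel=0.02)


class TestSmooth:
    def test_constant_invariant(self):
        out = smooth(_map(np.full((16, 16), 5.0)), sigma_px=1.0)
        assert np.allclose(out.values, 5.0)

    def test_impulse_kernel_normalized(self):
        values = np.zeros((33, 33))
        values[16, 16] = 1.0
        out = smooth(_map(values), sigma_px=1.0)
        assert out.values.sum() == pytest.approx(1.0, rel=1e-6)
        assert out.values.max() < 1.0

    def test_white_noise_sd_matches_2d_theory(self, rng):
        # Monte-Carlo oracle: smoothing white noise with a unit Gaussian
        # leaves SD ~ 1/(2 sqrt(pi) sigma)
        m = _map(rng.normal(0, 1, (256, 256)))
        out = smooth(m, sigma_px=1.0)
        assert out.values.std() == pytest.approx(1 / (2 * np.sqrt(np.pi)), rel=0.05)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth(_map(np.zeros((4, 4))), sigma_px=-1)


class TestRmsRoughness:
    def test_constant_crop_is_zero(self):
        assert rms_roughness(_map(np.full((32, 32), 9.0))) == pytest.approx(0.0, abs=1e-9)

    def test_sinusoid_rms_is_amplitude_over_sqrt2(self):
        # many periods along each row, so the quadratic row fit removes
        # almost nothing and the analytic RMS A/sqrt(2) survives realignment
        amp = 4.0
        cols = np.arange(128)
        wave = amp * np.sin(2 * np.pi * cols * 16 / 128)
        m = _map(np.tile(wave[None, :], (64, 1)))
        assert rms_roughness(m) == pytest.approx(amp / np.sqrt(2), rel=5e-3)

    def test_invariant_to_constant_and_row_quadratic(self, rng):
        base = rng.normal(0, 1.0, (64, 64))
        m = _map(base)
        x = np.linspace(-1, 1, 64)
        contaminated = base + 17.0 + rng.normal(0, 3, (64, 1)) * x**2
        m2 = _map(contaminated)
        assert rms_roughness(m2) == pytest.approx(rms_roughness(m), rel=1e-6)

    def test_region_cropping_and_errors(self, rng):
        m = _map(rng.normal(0, 1, (32, 32)))
        assert rms_roughness(m, region=(0, 16, 0, 16)) > 0
        with pytest.raises(ValueError):
            rms_roughness(m, region=(0, 64, 0, 16))

    def test_post_disruption_preset_near_reported_value(self):
        values = [rms_roughness(scene_from_preset("post_disruption", seed=s)[0]) for s in range(20)]
        assert np.median(values) == pytest.approx(3.1, rel=0.1)


class TestProfiles:
    def test_flat_profile_on_constant_image(self):
        m = _map(np.full((32, 32), 2.0))
        p = extract_profile(m, ((0, 31.0), (62.0, 31.0)))
        assert np.allclose(p.heights, 2.0)
        assert p.positions[0] == 0.0

    def test_diagonal_on_ramp_is_linear(self):
        # bilinear interpolation is exact on linear fields
        yy, xx = np.mgrid[0:64, 0:64]
        m = _map(0.5 * xx * 2.0)  # 0.5 nm per nm along x
        p = extract_profile(m, ((0.0, 0.0), (100.0, 100.0)))
        expected = 0.5 * (p.positions / np.sqrt(2))
        assert np.allclose(p.heights, expected, atol=1e-9)

    def test_endpoint_outside_rejected(self):
        m = _map(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            extract_profile(m, ((0, 0), (1000.0, 0)))

    def test_mac_rim_protrusion_recovered(self):
        hm, truth = scene_from_preset(
            "mac_patch", seed=1, corrugation_rms=0.0, scanline_amp=(0.0, 0.0, 0.0)
        )
        mx, my = truth.mac_points[0]
        w = (hm.shape[1] - 1) * hm.pixel_size
        p = extract_profile(hm, ((max(mx - 75, 0), my), (min(mx + 75, w), my)))
        assert feature_protrusion(p, peak_window=30) == pytest.approx(3.0, abs=0.2)


class TestFeatureProtrusion:
    def _profile(self, heights):
        h = np.asarray(heights, dtype=float)
        return Profile(positions=np.arange(len(h), dtype=float), heights=h, line=((0, 0), (1, 0)))

    def test_flat_profile_zero(self):
        assert feature_protrusion(self._profile(np.ones(50)), peak_window=10) == 0.0

    def test_single_bump(self):
        h = np.zeros(100)
        h[50] = 3.0
        assert feature_protrusion(self._profile(h), peak_window=10) == pytest.approx(3.0)

    def test_two_bumps_reports_taller(self):
        h = np.zeros(100)
        h[20] = 2.0
        h[70] = 5.0
        # oracle: brute-force max over all samples minus off-window median
        assert feature_protrusion(self._profile(h), peak_window=10) == pytest.approx(5.0)

    def test_window_covering_profile_rejected(self):
        with pytest.raises(ValueError):
            feature_protrusion(self._profile(np.zeros(10)), peak_window=100)


class TestConditioningRecovery:
    @pytest.mark.parametrize("rms", [0.5, 1.6, 3.1, 5.0])
    def test_chain_recovers_generator_roughness(self, rms):
        """plane_level -> align_rows -> smooth recovers the programmed RMS
        within 10% (median over 20 seeds)."""
        measured = []
        for seed in range(20):
            truth = SceneTruth(seed=seed, roughness_rms=rms, scanline_amp=(0.3, 0.3, 0.3))
            hm = render_height_image(truth, pixel_size=2.0, shape=(250, 250))
            conditioned = smooth(align_rows(plane_level(hm, mask_high=False), order=2))
            measured.append(rms_roughness(conditioned, realign=False))
        assert np.median(measured) == pytest.approx(rms, rel=0.10)

    @pytest.mark.parametrize("corrugation", [1.0, 1.5])
    def test_mac_protrusion_within_half_nm_under_corrugation(self, corrugation):
        """Rim height read from conditioned images (the flatten-base, row-align,
        smooth chain used for small height scans) is within 0.5 nm of the
        rendered rim height for corrugation RMS <= 1.5 nm."""
        values = []
        for seed in range(8):
            hm, truth = scene_from_preset(
                "mac_patch", seed=seed, corrugation_rms=corrugation
            )
            cond = smooth(align_rows(flatten_base(hm), order=2))
            w = (hm.shape[1] - 1) * hm.pixel_size
            for mx, my in truth.mac_points[:4]:
                p = extract_profile(cond, ((max(mx - 75, 0), my), (min(mx + 75, w), my)))
                values.append(feature_protrusion(p, peak_window=30))
        assert abs(np.median(values) - 3.0) < 0.5
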