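import math

import numpy as np
import pytest
import scipy.ndimage as ndi

from dirvessel import line_detector as ld
from dirvessel.dfb import DFBConfig, build_filter_bank, decompose
from dirvessel.errors import ConfigurationError, DegenerateInputError
from dirvessel.line_detector import (
    LineDetectorConfig,
    combine_scales,
    directional_msld,
    line_average,
    line_average_image,
    scale_response,
    standardize,
    window_average,
    window_average_image,
)


def naive_scale_response(image, center_angle, L, cfg):
    """Independent per-angle/per-sample gather implementation.

    Bilinear corner weights are gathered per pixel with explicit bounds
    checks; the window mean uses per-pixel slicing.  Only shares the
    edge-shrink policy with the production path, not its code.
    """
    h, w = image.shape
    angles = np.linspace(
        center_angle - cfg.angular_halfwidth,
        center_angle + cfg.angular_halfwidth,
        cfg.n_orientations_per_direction,
    )
    best = np.full((h, w), -np.inf)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    half = (L - 1) // 2
    for a in angles:
        num = np.zeros((h, w))
        den = np.zeros((h, w))
        for j in range(-half, half + 1):
            dr, dc = j * math.sin(a), j * math.cos(a)
            r0, c0 = math.floor(dr), math.floor(dc)
            fr, fc = dr - r0, dc - c0
            for rr, cc, wt in (
                (r0, c0, (1 - fr) * (1 - fc)),
                (r0, c0 + 1, (1 - fr) * fc),
                (r0 + 1, c0, fr * (1 - fc)),
                (r0 + 1, c0 + 1, fr * fc),
            ):
                if wt <= 0.0:
                    continue
                rr_idx = rows + rr
                cc_idx = cols + cc
                valid = (rr_idx >= 0) & (rr_idx < h) & (cc_idx >= 0) & (cc_idx < w)
                vals = image[np.clip(rr_idx, 0, h - 1), np.clip(cc_idx, 0, w - 1)]
                num += wt * np.where(valid, vals, 0.0)
                den += wt * valid
        best = np.maximum(best, num / den)
    halfw = cfg.window // 2
    wmean = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            wmean[r, c] = image[
                max(0, r - halfw) : r + halfw + 1, max(0, c - halfw) : c + halfw + 1
            ].mean()
    return best - wmean if cfg.eq4_sign == "minus" else best + wmean


class TestLineAverage:
    def test_constant_image(self):
        img = np.full((21, 21), 0.37)
        for angle in (0.0, 0.4, 1.1):
            assert line_average(img, (10, 10), angle, 9) == pytest.approx(0.37)

    def test_length_one_is_pixel_value(self, rng):
        img = rng.random((11, 11))
        assert line_average(img, (5, 7), 1.0, 1) == img[5, 7]

    def test_horizontal_ramp_hand_sum(self):
        img = np.arange(49, dtype=float).reshape(7, 7)
        expected = img[3, 1:6].mean()  # 5 horizontal neighbors of (3, 3)
        assert line_average(img, (3, 3), 0.0, 5) == pytest.approx(expected)

    def test_even_length_rejected(self):
        with pytest.raises(ConfigurationError):
            line_average(np.zeros((9, 9)), (4, 4), 0.0, 4)

    def test_image_variant_agrees_at_center(self, rng):
        img = rng.random((15, 15))
        for angle in (0.3, 1.2):
            raster = line_average_image(img, angle, 7)
            assert raster[7, 7] == pytest.approx(line_average(img, (7, 7), angle, 7), abs=1e-12)


class TestWindowAverage:
    def test_constant_and_window_one(self, rng):
        img = rng.random((9, 9))
        assert window_average(np.full((9, 9), 0.5), (4, 4), 5) == pytest.approx(0.5)
        assert window_average(img, (2, 3), 1) == img[2, 3]

    def test_full_window_mean(self, rng):
        img = rng.random((15, 15))
        assert window_average(img, (7, 7), 15) == pytest.approx(img.mean())
        raster = window_average_image(img, 15)
        assert raster[7, 7] == pytest.approx(img.mean())


class TestScaleResponse:
    def test_constant_image_zero_response(self):
        cfg = LineDetectorConfig()
        resp = scale_response(np.full((32, 32), 0.6), 0.0, 7, cfg)
        np.testing.assert_allclose(resp, 0.0, atol=1e-12)

    def test_bright_line_positive_response(self):
        cfg = LineDetectorConfig()
        img = np.full((31, 31), 0.2)
        img[15, :] = 0.9  # horizontal 1-px line
        resp = scale_response(img, 0.0, 15, cfg)
        assert (resp[15, 8:23] > 0).all()

    @pytest.mark.parametrize("L", [1, 7, 15])
    def test_matches_naive_oracle(self, rng, L):
        cfg = LineDetectorConfig()
        img = rng.random((32, 32))
        for angle in (0.0, np.pi / 8, 2.1):
            fast = scale_response(img, angle, L, cfg)
            slow = naive_scale_response(img, angle, L, cfg)
            assert np.abs(fast - slow).max() < 1e-9

    def test_plus_convention_selectable(self):
        cfg = LineDetectorConfig(eq4_sign="plus_as_printed")
        resp = scale_response(np.full((32, 32), 0.5), 0.0, 7, cfg)
        np.testing.assert_allclose(resp, 1.0, atol=1e-12)


class TestStandardize:
    def test_three_pixel_hand_case(self):
        resp = np.array([[1.0, 2.0, 3.0]])
        region = np.ones((1, 3), bool)
        out = standardize(resp, region)
        np.testing.assert_allclose(out, [[-1.22474487, 0.0, 1.22474487]], atol=1e-8)

    def test_idempotent_and_affine_invariant(self, rng):
        resp = rng.standard_normal((16, 16))
        region = np.ones((16, 16), bool)
        once = standardize(resp, region)
        np.testing.assert_allclose(standardize(once, region), once, atol=1e-12)
        np.testing.assert_allclose(standardize(3.2 * resp + 0.7, region), once, atol=1e-10)

    def test_region_contract(self, rng):
        resp = rng.standard_normal((32, 32)) * 4 + 2
        region = np.hypot(*np.mgrid[0:32, 0:32] - 15.5) < 14
        out = standardize(resp, region)
        assert abs(out[region].mean()) < 1e-9
        assert abs(out[region].std() - 1.0) < 1e-9
        assert (out[~region] == 0).all()

    def test_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            standardize(np.full((4, 4), 1.0), np.ones((4, 4), bool))


class TestCombineScales:
    def test_single_zero_response_with_igc(self):
        igc = np.full((8, 8), 0.5)
        out = combine_scales([np.zeros((8, 8))], igc, np.ones((8, 8), bool))
        np.testing.assert_allclose(out, 0.25)

    def test_default_divisor_is_nine(self, rng):
        igc = rng.random((8, 8))
        responses = [rng.standard_normal((8, 8)) for _ in range(8)]
        out = combine_scales(responses, igc, np.ones((8, 8), bool))
        expected = (np.sum(responses, axis=0) + igc) / 9.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_scales([], np.zeros((4, 4)), np.ones((4, 4), bool))


class TestDirectionalMSLD:
    def test_runs_one_scale_response_per_scale(self, monkeypatch, rng):
        calls = []
        original = ld.scale_response

        def counting(*args, **kwargs):
            calls.append(args[2])
            return original(*args, **kwargs)

        monkeypatch.setattr(ld, "scale_response", counting)
        img = rng.random((32, 32))
        region = np.ones((32, 32), bool)
        directional_msld(img, 0.0, img, region)
        assert calls == list(LineDetectorConfig().scale_list)

    def test_line_phantom_coverage(self):
        """Top-decile responses in the aligned sub-band cover the line."""
        theta = math.pi / 8
        rr, cc = np.mgrid[0:128, 0:128]
        d = -(rr - 63.5) * math.cos(theta) + (cc - 63.5) * math.sin(theta)
        igc = 0.3 + 0.5 * np.exp(-0.5 * (d / 1.2) ** 2)
        bank = build_filter_bank((128, 128), DFBConfig())
        stack = decompose(igc, bank)
        region = np.hypot(rr - 63.5, cc - 63.5) < 60
        resp = directional_msld(stack[1], bank.center_angles[1], igc, region, LineDetectorConfig())
        line_px = (np.abs(d) < 1.0) & region
        top = resp >= np.quantile(resp[region], 0.9)
        assert (top & line_px).sum() / line_px.sum() >= 0.8

    def test_pure_noise_response_centered(self, rng):
        noise = rng.standard_normal((64, 64)) * 0.01
        region = np.ones((64, 64), bool)
        resp = directional_msld(noise, 0.0, np.full((64, 64), 0.5), region, LineDetectorConfig())
        vals = resp[region]
        iqr = np.subtract(*np.percentile(vals, [75, 25]))
        assert abs(np.median(vals) - vals.mean()) < 0.2 * iqr

    def test_rotation_covariance(self):
        """Rotating the scene by one band spacing and shifting the band
        index yields the same response up to interpolation error.

        The square grid breaks exact covariance (DFT anisotropy, exact
        vs bilinear taps), so the bound is relative to the response
        range, with a correlation floor.
        """
        n = 96
        rr, cc = np.mgrid[0:n, 0:n]
        c0 = (n - 1) / 2
        region = np.hypot(rr - c0, cc - c0) <= 0.47 * n
        bank = build_filter_bank((n, n), DFBConfig())
        cfg = LineDetectorConfig()
        resps = []
        for i, theta in enumerate((0.0, math.pi / 8)):
            d = -(rr - c0) * math.cos(theta) + (cc - c0) * math.sin(theta)
            img = 0.3 + 0.4 * np.exp(-0.5 * (d / 1.2) ** 2)
            stack = decompose(img, bank)
            resps.append(directional_msld(stack[i], bank.center_angles[i], img, region, cfg))
        rot = ndi.rotate(resps[0], -22.5, reshape=False, order=3)
        inner = np.hypot(rr - c0, cc - c0) <= 0.35 * n
        span = resps[1][inner].max() - resps[1][inner].min()
        assert np.abs(rot - resps[1])[inner].max() < 0.05 * span
        assert np.corrcoef(rot[inner], resps[1][inner])[0, 1] > 0.99

    def test_central_light_reflex_robustness(self):
        """A dimmed midline (vessel reflex) keeps a positive response:
        the winning line runs along the midline and still beats the
        window mean."""
        img = np.full((33, 33), 0.2)
        img[14:19, :] = 0.8
        img[16, :] = 0.55  # reflex: midline dimmer than the vessel body
        cfg = LineDetectorConfig()
        resp = scale_response(img, 0.0, 15, cfg)
        assert (resp[16, 10:23] > 0).all()
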