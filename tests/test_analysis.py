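"""Selectivity metrics, decoding, and the path-integration speed ratio."""

import numpy as np
import pytest

from cannsim import analysis
from cannsim.analysis import (
    DecoderModel,
    SelectivityThresholds,
    bin_by_heading,
    circular_error,
    decode_hd,
    fit_hd_decoder,
    hd_selectivity,
    path_integration_speed_ratio,
    place_field_stats,
    unwrap_series,
)

TWO_PI = 2 * np.pi


def gaussian_curve(n_bins=360, mu=1.0, sigma=np.pi / 9, amp=1.0):
    angles = TWO_PI * (np.arange(n_bins) + 0.5) / n_bins
    d = np.abs(angles - mu)
    d = np.minimum(d, TWO_PI - d)
    return amp * np.exp(-(d**2) / (2 * sigma**2))


class TestHdSelectivity:
    def test_flat_curve_scores_zero(self):
        res = hd_selectivity(np.ones(360))
        assert res.score == pytest.approx(0.0, abs=1e-12)
        assert not res.is_selective

    def test_single_bin_scores_one(self):
        curve = np.zeros(360)
        curve[42] = 0.8
        res = hd_selectivity(curve)
        assert res.score == pytest.approx(1.0)
        assert res.is_selective

    def test_gaussian_matches_bruteforce_resultant(self):
        """Resultant of a Gaussian tuning curve equals the brute-force sum,
        approximately exp(-sigma^2/2) for narrow widths."""
        sigma = np.pi / 9
        curve = gaussian_curve(sigma=sigma)
        res = hd_selectivity(curve)
        angles = TWO_PI * (np.arange(360) + 0.5) / 360
        brute = abs(np.sum(curve * np.exp(1j * angles))) / curve.sum()
        assert res.score == pytest.approx(brute, abs=1e-12)
        assert res.score == pytest.approx(np.exp(-(sigma**2) / 2), abs=1e-3)

    def test_all_zero_curve_policy(self):
        res = hd_selectivity(np.zeros(360))
        assert res.score == 0.0 and res.preferred is None and not res.is_selective

    def test_scale_and_rotation_invariance(self):
        curve = gaussian_curve(mu=2.0)
        r1 = hd_selectivity(curve)
        r2 = hd_selectivity(10.0 * curve)
        assert r1.score == pytest.approx(r2.score)
        shift = 90
        r3 = hd_selectivity(np.roll(curve, shift))
        assert r3.score == pytest.approx(r1.score, abs=1e-9)
        expected = (r1.preferred + shift * TWO_PI / 360) % TWO_PI
        assert circular_error(r3.preferred, expected) < 1e-6

    def test_split_tuning_fails_unimodality(self):
        curve = gaussian_curve(mu=1.0) + gaussian_curve(mu=1.0 + np.pi)
        res = hd_selectivity(curve)
        assert res.extras["dominant_share"] == pytest.approx(0.5, abs=0.01)
        assert not res.is_selective


class TestPlaceFieldStats:
    def test_uniform_map_not_selective(self):
        res = place_field_stats(np.full((10, 10), 0.5))
        assert res.score == pytest.approx(1.0)
        assert not res.is_selective

    def test_single_bin_peak_area(self):
        m = np.zeros((10, 10))
        m[3, 7] = 1.0
        res = place_field_stats(m)
        assert res.extras["field_area_fraction"] == pytest.approx(1 / 100)
        assert res.is_selective

    def test_gaussian_bump_matches_bruteforce_component(self):
        """Stats of a 2D Gaussian bump agree with brute-force enumeration of
        the half-peak connected component."""
        ys, xs = np.mgrid[0:10, 0:10]
        m = np.exp(-((xs - 6.0) ** 2 + (ys - 3.0) ** 2) / (2 * 1.2**2))
        res = place_field_stats(m)
        # brute-force flood fill from the peak over >= half-peak bins
        above = m >= 0.5 * m.max()
        seen = {(3, 6)}
        frontier = [(3, 6)]
        while frontier:
            y, x = frontier.pop()
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < 10 and 0 <= xx < 10 and above[yy, xx] and (yy, xx) not in seen:
                    seen.add((yy, xx))
                    frontier.append((yy, xx))
        assert res.extras["field_area_fraction"] == pytest.approx(len(seen) / 100)
        assert res.score == pytest.approx(m.max() / m.mean())
        cx, cy = res.preferred
        assert cx == pytest.approx(6.0, abs=0.2) and cy == pytest.approx(3.0, abs=0.2)
        assert res.is_selective

    def test_scale_invariance(self):
        ys, xs = np.mgrid[0:8, 0:8]
        m = np.exp(-((xs - 4) ** 2 + (ys - 4) ** 2) / 4.0)
        r1, r2 = place_field_stats(m), place_field_stats(5.0 * m)
        assert r1.score == pytest.approx(r2.score)
        assert r1.extras["field_area_fraction"] == r2.extras["field_area_fraction"]

    def test_all_zero_map(self):
        assert not place_field_stats(np.zeros((5, 5))).is_selective

    def test_low_rate_map_not_selective(self):
        m = np.zeros((10, 10))
        m[2, 2] = 0.01  # peaked but essentially silent
        assert not place_field_stats(m).is_selective


class TestBinning:
    def test_flat_rates_give_flat_curve(self):
        rng = np.random.default_rng(0)
        headings = rng.uniform(0, TWO_PI, 5000)
        rates = np.full((5000, 3), 0.7)
        curves = bin_by_heading(rates, headings, 36)
        assert curves.shape == (3, 36)
        assert np.allclose(curves, 0.7)

    def test_empty_bins_interpolated(self):
        headings = np.array([0.01, 0.02, np.pi, np.pi + 0.01])
        rates = np.array([[1.0], [1.0], [0.2], [0.2]])
        curves = bin_by_heading(rates, headings, 8)
        assert np.all(np.isfinite(curves))


class TestDecoder:
    def _linear_rates(self, n=2000, n_cells=50, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, TWO_PI, n)
        A = rng.normal(size=(2, n_cells))
        b = rng.normal(size=n_cells)
        R = np.column_stack([np.sin(theta), np.cos(theta)]) @ A + b
        R += noise * rng.normal(size=R.shape)
        return R, theta

    def test_linear_recovery_oracle(self):
        """Rates that are exact linear functions of (sin, cos) decode with
        near-zero circular error on held-out samples."""
        R, theta = self._linear_rates()
        model = fit_hd_decoder(R[:1500], theta[:1500])
        err = circular_error(decode_hd(model, R[1500:]), theta[1500:])
        assert np.mean(err) < 0.01

    def test_constant_rates_collapse_to_circular_mean(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0.4, 0.6, 500)  # concentrated headings
        R = np.ones((500, 10))
        model = fit_hd_decoder(R, theta)
        pred = decode_hd(model, np.ones((5, 10)))
        mean_dir = np.angle(np.sum(np.exp(1j * theta))) % TWO_PI
        assert np.all(circular_error(pred, mean_dir) < 0.05)

    def test_deterministic_refit(self):
        R, theta = self._linear_rates(noise=0.01, seed=2)
        m1 = fit_hd_decoder(R, theta)
        m2 = fit_hd_decoder(R, theta)
        assert np.array_equal(m1._models[0].coef_, m2._models[0].coef_)

    def test_untrained_prediction_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            DecoderModel().predict(np.ones((3, 4)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_hd_decoder(np.ones((1, 4)), np.array([0.0]))

    def test_empty_input_empty_output(self):
        R, theta = self._linear_rates(n=100)
        model = fit_hd_decoder(R, theta)
        assert decode_hd(model, np.empty((0, R.shape[1]))).size == 0

    def test_literal_linear_mode_fits(self):
        R, theta = self._linear_rates(n=500, seed=3)
        model = fit_hd_decoder(R, np.sort(theta), mode="literal_linear")
        assert model.trained


class TestSpeedRatio:
    def test_identity_and_half_speed(self):
        t = np.linspace(10, 20, 500)
        truth = (0.8 * t) % TWO_PI
        assert path_integration_speed_ratio(truth, truth, t, (10, 20)) == pytest.approx(1.0)
        half = (0.4 * t) % TWO_PI
        assert path_integration_speed_ratio(half, truth, t, (10, 20)) == pytest.approx(0.5, abs=1e-6)

    def test_sign_correct_for_clockwise_truth(self):
        t = np.linspace(0, 10, 300)
        truth = (-1.0 * t) % TWO_PI  # clockwise
        decoded = (-0.7 * t) % TWO_PI  # clockwise, slower
        ratio = path_integration_speed_ratio(decoded, truth, t, (0, 10))
        assert ratio == pytest.approx(0.7, abs=1e-6)
        assert ratio > 0

    def test_zero_truth_slope_rejected(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(ValueError, match="zero"):
            path_integration_speed_ratio(t % TWO_PI, np.full(100, 1.0), t, (0, 5))

    def test_unwrap_shortest_arc(self):
        theta = np.array([6.2, 0.1, 0.3, 6.1])
        u = unwrap_series(theta)
        assert np.allclose(np.diff(u), [0.1832, 0.2, -0.4832], atol=1e-3)
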