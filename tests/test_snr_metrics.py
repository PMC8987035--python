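import numpy as np
import pytest
from scipy import ndimage

from lowvoltcount.counting_filters import (WeightProfile,
                                           apply_radial_weight,
                                           render_patterns, render_points)
from lowvoltcount.snr_metrics import (EdgeFitError, RadialCurve, dqe,
                                      fit_edge, frc, fsc_to_snr,
                                      knife_edge_mtf, load_curve, nps,
                                      save_curve, snr_gain_fit, snr_to_fsc)


class TestFrc:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(0, 1, (32, 32))
        np.testing.assert_allclose(frc(x, x).values, 1.0, atol=1e-12)

    def test_anticorrelation_is_minus_one(self, rng):
        x = rng.normal(0, 1, (32, 32))
        np.testing.assert_allclose(frc(x, -x).values, -1.0, atol=1e-12)

    def test_independent_noise_near_zero(self, rng):
        a = rng.normal(0, 1, (64, 64))
        b = rng.normal(0, 1, (64, 64))
        c = frc(a, b)
        assert np.all(np.abs(c.values) < 3.0 / np.sqrt(c.n_terms))

    def test_zero_power_shell_warns(self):
        with pytest.warns(UserWarning):
            c = frc(np.zeros((16, 16)), np.zeros((16, 16)))
        np.testing.assert_allclose(c.values, 0.0)

    def test_halfset_consistency_rises_with_events(self, rng):
        """More electrons per half-set -> higher FRC (consistency)."""
        from conftest import probe_specimen
        lam = probe_specimen(64, probes=((0.15, 30),), amplitude=0.4)
        mids = []
        for n in (400, 8000):
            halves = []
            for _ in range(2):
                # rejection-sample positions from the pattern
                pos = []
                while len(pos) < n:
                    x, y = rng.uniform(0, 63, 2)
                    if rng.random() < lam[int(round(y)), int(round(x))]:
                        pos.append((x, y))
                halves.append(render_points(pos, (64, 64), 1).array)
            c = frc(halves[0], halves[1])
            mids.append(c.values[int(np.argmin(np.abs(c.shells - 0.15)))])
        assert mids[1] > mids[0] > 0


class TestFscSnr:
    def test_worked_values_exact(self):
        assert fsc_to_snr(0.80) == pytest.approx(8.00, abs=1e-12)
        assert fsc_to_snr(0.68) == pytest.approx(4.25, abs=1e-12)
        assert fsc_to_snr(0.0) == 0.0

    def test_fsc_one_raises(self):
        with pytest.raises(ValueError):
            fsc_to_snr(1.0)

    def test_monotone_and_inverse_identity(self):
        f = np.linspace(-0.95, 0.95, 101)
        s = fsc_to_snr(f)
        assert np.all(np.diff(s) > 0)
        np.testing.assert_allclose(snr_to_fsc(s), f, atol=1e-12)

    def test_curve_input(self):
        c = RadialCurve(np.array([0.1, 0.2]), np.array([0.8, 0.68]))
        out = fsc_to_snr(c)
        np.testing.assert_allclose(out.values, [8.0, 4.25])


class TestNps:
    def test_all_zero_input(self):
        c = nps(np.zeros((32, 32)))
        np.testing.assert_allclose(c.values, 0.0)

    def test_single_structured_realization_warns(self):
        ramp = np.outer(np.ones(32), np.linspace(0, 10, 32))
        with pytest.warns(UserWarning, match="flat"):
            nps(ramp)

    def test_point_counting_is_white_at_dose(self, rng):
        imgs = []
        d = 0.05
        for _ in range(128):
            n = rng.poisson(d * 64 * 64)
            pos = np.column_stack([rng.uniform(0, 64, n),
                                   rng.uniform(0, 64, n)])
            imgs.append(render_points(pos, (64, 64), 1).array)
        c = nps(imgs)
        assert c.values.mean() == pytest.approx(d, rel=0.05)
        # per-shell chi^2 sampling band: sd of a shell mean is
        # sqrt(2 / (n_terms * n_realizations)) relative
        band = 4.0 * np.sqrt(2.0 / (c.n_terms * len(imgs)))
        assert np.all(np.abs(c.values / c.values.mean() - 1.0) < band)

    def test_uniform_pattern_counting_suppresses_high_frequency(self, rng):
        """Spreading each event over a 5-pixel plus-pattern acts as a
        natural low-pass on the noise."""
        pat = {(0, 0): 0.2, (1, 0): 0.2, (-1, 0): 0.2, (0, 1): 0.2,
               (0, -1): 0.2}
        imgs = []
        for _ in range(64):
            n = rng.poisson(150)
            evs = [((float(x), float(y)), pat)
                   for x, y in rng.integers(3, 61, (n, 2))]
            imgs.append(render_patterns(evs, (64, 64), 1).array)
        c = nps(imgs)
        lo = c.values[:len(c) // 4].mean()
        hi = c.values[3 * len(c) // 4:].mean()
        assert hi < 0.5 * lo

    def test_weighting_scales_nps_by_w_squared(self, rng):
        """Parseval: multiplying the spectrum by w multiplies NPS by w^2."""
        shells = np.linspace(0, 0.5, 33)[1:]
        w = 1.0 - 0.8 * shells / 0.5
        prof = WeightProfile(RadialCurve(shells, w))
        raw, weighted = [], []
        for _ in range(96):
            n = rng.poisson(200)
            pos = np.column_stack([rng.uniform(0, 64, n),
                                   rng.uniform(0, 64, n)])
            img = render_points(pos, (64, 64), 1)
            raw.append(img.array)
            weighted.append(apply_radial_weight(img, prof).array)
        ratio = nps(weighted).values / nps(raw).values
        np.testing.assert_allclose(ratio, w**2, rtol=0.02, atol=0.004)


def _ideal_edge_image(n=256, angle_deg=3.0):
    yy, xx = np.mgrid[0:n, 0:n]
    a = np.radians(angle_deg)
    dist = ((xx - (n - 1) / 2) - np.tan(a) * (yy - (n - 1) / 2)) * np.cos(a)
    return np.clip(dist + 0.5, 0, 1)     # pixel-aperture coverage


class TestKnifeEdgeMtf:
    def test_normalized_at_low_frequency(self):
        c = knife_edge_mtf(_ideal_edge_image())
        assert c.values[0] > 0.99

    def test_pixel_aperture_nyquist_two_over_pi(self):
        c = knife_edge_mtf(_ideal_edge_image())
        v = np.interp(0.5, c.shells, c.values)
        assert v == pytest.approx(2 / np.pi, rel=0.02)

    def test_gaussian_blur_closed_form(self):
        img = ndimage.gaussian_filter(_ideal_edge_image(), 1.0)
        c = knife_edge_mtf(img)
        expected = np.abs(np.sinc(c.shells)) * \
            np.exp(-2 * np.pi**2 * c.shells**2)
        sel = expected >= 0.05
        np.testing.assert_allclose(c.values[sel], expected[sel], rtol=0.02)

    def test_edge_angle_recovered(self):
        c = knife_edge_mtf(_ideal_edge_image(angle_deg=2.5))
        assert c.meta["edge_angle_deg"] == pytest.approx(2.5, abs=0.1)

    def test_untilted_edge_rejected(self):
        with pytest.raises(EdgeFitError):
            fit_edge(_ideal_edge_image(angle_deg=0.0))


class TestDqe:
    def _white_nps(self, rng, jitter=0.0, d=0.05, n=64, reps=96):
        imgs = []
        for _ in range(reps):
            k = rng.poisson(d * n * n)
            pos = np.column_stack([rng.uniform(0, n, k),
                                   rng.uniform(0, n, k)])
            if jitter:
                pos = np.clip(pos + rng.normal(0, jitter, pos.shape),
                              0, n - 1e-6)
            imgs.append(render_points(pos, (n, n), 1).array)
        return nps(imgs)

    def test_ideal_counter_unity_at_low_frequency(self, rng):
        n = self._white_nps(rng)
        mtf = RadialCurve(n.shells, np.ones(len(n)))
        c = dqe(mtf, n, counted_dose=0.05)
        assert c.values[:4].mean() == pytest.approx(1.0, rel=0.05)
        assert c.meta["normalization"] == 1.0

    def test_linear_in_detected_fraction(self, rng):
        n = self._white_nps(rng)
        mtf = RadialCurve(n.shells, np.ones(len(n)))
        c = dqe(mtf, n, counted_dose=0.05, detected_fraction=0.5)
        assert c.values[:4].mean() == pytest.approx(0.5, rel=0.05)

    def test_position_jitter_lowers_nyquist_dqe(self, rng):
        sigma = 0.5
        n_ideal = self._white_nps(rng)
        n_jit = self._white_nps(rng, jitter=sigma)
        ones = RadialCurve(n_ideal.shells, np.ones(len(n_ideal)))
        jitter_mtf = RadialCurve(
            n_jit.shells, np.exp(-2 * np.pi**2 * sigma**2 * n_jit.shells**2))
        ideal = dqe(ones, n_ideal, 0.05)
        jittered = dqe(jitter_mtf, n_jit, 0.05)
        assert jittered.values[-1] < 0.5 * ideal.values[-1]

    def test_shell_mismatch_raises(self, rng):
        n = self._white_nps(rng)
        mtf = RadialCurve(n.shells[:-1], np.ones(len(n) - 1))
        with pytest.raises(ValueError):
            dqe(mtf, n, 0.05)


class TestSnrGainFit:
    def _curve(self, vals):
        shells = np.linspace(0, 0.5, len(vals) + 1)[1:]
        return RadialCurve(shells, np.asarray(vals, dtype=float))

    def test_identical_curves_ratio_one(self):
        c = self._curve(np.linspace(10, 1, 20))
        half, nyq, slope, icpt = snr_gain_fit(c, c)
        assert half == pytest.approx(1.0, abs=1e-9)
        assert nyq == pytest.approx(1.0, abs=1e-9)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_doubled_snr(self):
        c = self._curve(np.linspace(10, 1, 20))
        half, nyq, _, _ = snr_gain_fit(c.scaled(2.0), c)
        assert half == pytest.approx(2.0, abs=1e-9)
        assert nyq == pytest.approx(2.0, abs=1e-9)

    def test_exact_linear_ratio(self):
        base = self._curve(np.full(40, 5.0))
        frac = base.shells / 0.5
        grown = RadialCurve(base.shells, base.values * (1 + frac))
        _, nyq, _, _ = snr_gain_fit(grown, base, fit_lo=0.2, fit_hi=0.9)
        assert nyq == pytest.approx(2.0, rel=0.01)

    def test_too_few_shells_raises(self):
        c = self._curve([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            snr_gain_fit(c, c, fit_lo=0.45, fit_hi=0.55)


class TestCurveUtilities:
    def test_threshold_crossing_interpolates(self):
        c = RadialCurve(np.array([0.1, 0.2, 0.3]),
                        np.array([0.9, 0.5, 0.1]))
        assert c.threshold_crossing(0.143) == pytest.approx(
            0.2 + (0.5 - 0.143) / 0.4 * 0.1)

    def test_save_load_round_trip(self, tmp_path):
        c = RadialCurve(np.array([0.1, 0.2]), np.array([1.5, -0.3]),
                        np.array([10, 20]), {"note": "x"})
        save_curve(c, tmp_path / "c.json")
        back = load_curve(tmp_path / "c.json")
        np.testing.assert_allclose(back.shells, c.shells)
        np.testing.assert_allclose(back.values, c.values)
        assert back.meta["note"] == "x"
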