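import numpy as np
import pytest

from lowvoltcount.counting_filters import (CountedImage, WeightProfile,
                                           apply_radial_weight,
                                           count_clusters, count_stack,
                                           gcf_position, mcf_position,
                                           pca_pattern, pvf_position,
                                           render_patterns, render_points,
                                           snr_weight_profile)
from lowvoltcount.frames_io import FrameStack
from lowvoltcount.snr_metrics import RadialCurve

from conftest import make_cluster

SPEC_POWS = [0, 0.25, -0.25, 0.5, -0.5, 0.75, -0.75, 1, -1,
             1.25, -1.25, 1.5, -1.5, 2, -2, 3, -3]


class TestPositions:
    def test_mcf_symmetric_pair(self):
        c = make_cluster({(0, 0): 1.0, (1, 0): 1.0})
        assert mcf_position(c) == (0.5, 0.0)

    def test_mcf_weighted_mean(self):
        c = make_cluster({(2, 3): 3.0, (3, 3): 1.0})
        assert mcf_position(c) == (2.25, 3.0)

    def test_single_pixel_all_rules_agree(self):
        c = make_cluster({(7, 4): 2.0})
        assert mcf_position(c) == pvf_position(c) == gcf_position(c) \
            == (7.0, 4.0)

    def test_pvf_simple_max(self):
        c = make_cluster({(2, 3): 10.0, (2, 4): 5.0})
        assert pvf_position(c) == (2.0, 3.0)

    def test_pvf_tie_broken_by_distance_to_mass_centre(self):
        # mass centre at x = 7/11 = 0.636: (1,0) is nearer than (0,0)
        c = make_cluster({(0, 0): 5.0, (1, 0): 5.0, (2, 0): 1.0})
        assert pvf_position(c) == (1.0, 0.0)

    def test_pvf_exact_tie_lexicographic(self):
        c = make_cluster({(0, 0): 5.0, (1, 0): 5.0})
        # mass centre at 0.5: both equidistant -> smallest (y, x)
        assert pvf_position(c) == (0.0, 0.0)

    def test_gcf_ignores_values(self):
        assert gcf_position(make_cluster({(0, 0): 100.0, (2, 0): 1.0})) \
            == (1.0, 0.0)

    def test_gcf_full_block_centre(self):
        c = make_cluster({(x, y): 1.0 for x in range(3) for y in range(3)})
        assert gcf_position(c) == (1.0, 1.0)

    def test_symmetric_cluster_rules_coincide(self):
        c = make_cluster({(4, 5): 2.0, (6, 5): 2.0, (5, 4): 2.0,
                          (5, 6): 2.0, (5, 5): 9.0})
        assert mcf_position(c) == gcf_position(c) == pvf_position(c) \
            == (5.0, 5.0)


class TestPcaPattern:
    def test_pow_zero_uniform(self):
        c = make_cluster({(i, 0): float(i + 1) for i in range(5)})
        pat = pca_pattern(c, 0)
        assert all(v == pytest.approx(0.2) for v in pat.values())

    def test_pow_one_proportional(self):
        pat = pca_pattern(make_cluster({(0, 0): 3.0, (1, 0): 1.0}), 1)
        assert sorted(pat.values()) == [pytest.approx(0.25),
                                        pytest.approx(0.75)]

    def test_pow_two_squares(self):
        pat = pca_pattern(make_cluster({(0, 0): 3.0, (1, 0): 1.0}), 2)
        assert sorted(pat.values()) == [pytest.approx(0.1),
                                        pytest.approx(0.9)]

    @pytest.mark.parametrize("pow", SPEC_POWS)
    def test_all_documented_pows_normalize(self, pow, rng):
        c = make_cluster({(int(x), int(y)): float(v)
                          for (x, y), v in zip(rng.integers(0, 9, (6, 2)),
                                               rng.uniform(0.5, 50, 6))})
        pat = pca_pattern(c, pow)
        assert sum(pat.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in pat.values())

    def test_overflow_raises(self):
        c = make_cluster({(0, 0): 1e200, (1, 0): 1e-6})
        with pytest.raises(ValueError):
            pca_pattern(c, 3)


class TestRenderPoints:
    def test_documented_mapping(self):
        img = render_points([(10.3, 5.9)], (16, 16), sr_factor=2)
        assert img.array[11, 20] == 1.0
        assert img.array.sum() == 1.0

    def test_conservation(self, rng):
        pos = np.column_stack([rng.uniform(0, 16, 200),
                               rng.uniform(0, 16, 200)])
        img = render_points(pos, (16, 16), sr_factor=2)
        assert img.array.sum() == pytest.approx(200)
        assert img.n_events == 200

    def test_sr2_block_sum_equals_sr1(self, rng):
        pos = np.column_stack([rng.uniform(0, 12, 300),
                               rng.uniform(0, 12, 300)])
        a = render_points(pos, (12, 12), sr_factor=1).array
        b = render_points(pos, (12, 12), sr_factor=2).array
        blocked = b.reshape(12, 2, 12, 2).sum(axis=(1, 3))
        np.testing.assert_allclose(blocked, a)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            render_points([(20.0, 5.0)], (16, 16), 1)


class TestRenderPatterns:
    def test_uniform_five_pixel_pattern(self):
        pat = {(-1, 0): 0.2, (0, 0): 0.2, (1, 0): 0.2, (0, -1): 0.2,
               (0, 1): 0.2}
        img = render_patterns([((8.0, 8.0), pat)], (16, 16), 1)
        assert img.array.sum() == pytest.approx(1.0)
        assert img.array[8, 8] == pytest.approx(0.2)
        assert img.array[8, 7] == pytest.approx(0.2)

    def test_mixture_conserves_count(self, rng):
        events = []
        for i in range(50):
            if i % 2:
                events.append(((float(rng.uniform(2, 13)),
                                float(rng.uniform(2, 13))), None))
            else:
                events.append(((float(rng.integers(3, 12)),
                                float(rng.integers(3, 12))),
                               {(0, 0): 0.5, (1, 0): 0.5}))
        img = render_patterns(events, (16, 16), 2)
        assert img.array.sum() == pytest.approx(50)

    def test_high_pow_approaches_peak_rendering(self):
        c = make_cluster({(5, 5): 10.0, (6, 5): 6.0, (5, 6): 3.0,
                          (6, 6): 2.0, (7, 5): 1.0})
        pat = pca_pattern(c, 50)
        img_pat = render_patterns([(mcf_position(c), pat)], (12, 12), 1)
        img_pt = render_points([pvf_position(c)], (12, 12), 1)
        np.testing.assert_allclose(img_pat.array, img_pt.array, atol=1e-6)


def _flat_curves(n=12, val=1.0):
    shells = np.linspace(0, 0.5, n + 1)[1:]
    return RadialCurve(shells, np.full(n, val))


class TestSnrWeighting:
    def test_identity_weight(self):
        w = snr_weight_profile(_flat_curves(), _flat_curves(),
                               _flat_curves(), _flat_curves())
        np.testing.assert_allclose(w.curve.values, 1.0)

    def test_square_root_of_snr_ratio(self):
        w = snr_weight_profile(_flat_curves(val=1.0), _flat_curves(val=4.0),
                               _flat_curves(), _flat_curves())
        np.testing.assert_allclose(w.curve.values, 2.0)

    def test_worked_snr_values(self):
        # per-shell SNRs 8.00 and 4.25 from the FSC worked example
        w = snr_weight_profile(_flat_curves(val=4.25), _flat_curves(val=8.00),
                               _flat_curves(), _flat_curves())
        np.testing.assert_allclose(w.curve.values, 1.372, atol=5e-4)

    def test_shell_mismatch_raises(self):
        a = _flat_curves(12)
        b = _flat_curves(10)
        with pytest.raises(ValueError):
            snr_weight_profile(a, b, a, a)

    def test_nonpositive_shells_clamped_with_warning(self):
        bad = _flat_curves()
        bad.values[3] = -1.0
        with pytest.warns(UserWarning):
            w = snr_weight_profile(bad, _flat_curves(), _flat_curves(),
                                   _flat_curves())
        assert w.curve.values[3] == 0.0


class TestApplyRadialWeight:
    def test_identity_profile_is_noop(self, rng):
        img = CountedImage(rng.random((32, 32)), 1, 0)
        out = apply_radial_weight(img, WeightProfile.identity())
        np.testing.assert_allclose(out.array, img.array, atol=1e-9)

    def test_boxcar_lowpass_matches_fft_oracle(self, rng):
        arr = rng.random((32, 32))
        cut = 0.25
        shells = np.linspace(0, 0.5, 65)[1:]
        prof = WeightProfile(RadialCurve(shells, (shells <= cut) * 1.0))
        out = apply_radial_weight(CountedImage(arr, 1, 0), prof)
        # oracle: direct FFT mask with the same linear interpolation of w
        fy = np.fft.fftfreq(32)[:, None]
        fx = np.fft.fftfreq(32)[None, :]
        u = np.hypot(fy, fx)
        w = np.interp(u, shells, (shells <= cut) * 1.0)
        w.flat[0] = 1.0
        expected = np.fft.ifft2(np.fft.fft2(arr) * w).real
        np.testing.assert_allclose(out.array, expected, atol=1e-10)

    def test_real_output_and_dc_conservation(self, rng):
        arr = rng.random((24, 24))
        prof = WeightProfile.from_scalar(0.3)
        out = apply_radial_weight(CountedImage(arr, 1, 0), prof)
        assert np.isrealobj(out.array)
        # w(0) forced to 1: total mass conserved
        assert out.array.sum() == pytest.approx(arr.sum(), rel=1e-9)


def _stack_with_clusters(rng, n_single=20):
    """Frames whose clusters are all single pixels (bright, isolated)."""
    frames = np.zeros((2, 48, 48), dtype=np.float32)
    for f in range(2):
        xs = rng.choice(np.arange(4, 44, 4), n_single // 2, replace=False)
        ys = rng.choice(np.arange(4, 44, 4), n_single // 2, replace=False)
        frames[f, ys, xs] = 200.0
    return FrameStack(frames)


class TestCountStack:
    def test_single_pixel_clusters_make_methods_agree(self, rng):
        stack = _stack_with_clusters(rng)
        images = {}
        for meth in ("MCF", "PVF", "GCF", "Hybrid"):
            img, _ = count_stack(stack, meth, sr_factor=2)
            images[meth] = img.array
        for meth in ("PVF", "GCF", "Hybrid"):
            np.testing.assert_allclose(images[meth], images["MCF"])

    def test_hybrid_spreads_large_cluster_uniformly(self):
        frame = np.zeros((24, 24), dtype=np.float32)
        # plus-shaped 5-pixel cluster
        frame[10, 10] = 300.0
        frame[9, 10] = frame[11, 10] = frame[10, 9] = frame[10, 11] = 250.0
        img, stream = count_stack(FrameStack(frame[None]), "Hybrid",
                                  sr_factor=1)
        assert len(stream) == 1
        assert stream.records[0].size_class == "large"
        nz = img.array[img.array > 0]
        np.testing.assert_allclose(nz, 0.2)
        assert nz.size == 5

    @pytest.mark.parametrize("method", ["MCF", "PVF", "GCF", "PCA",
                                        "Hybrid", "WPF"])
    def test_conservation_every_method(self, method, rng):
        from lowvoltcount.synth_frames import DetectorModel, \
            generate_frame_stack
        model = DetectorModel(dims=(64, 64))
        stack, _ = generate_frame_stack(model, 0.01, 3, seed=5)
        kwargs = {}
        if method == "WPF":
            kwargs["weight_profile"] = WeightProfile.identity()
        img, stream = count_stack(stack, method, sr_factor=2, **kwargs)
        assert len(stream) > 0
        assert img.array.sum() == pytest.approx(len(stream), rel=1e-6)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            count_stack(FrameStack(np.zeros((1, 16, 16))), "XYZ")

    def test_wpf_needs_profile(self):
        with pytest.raises(ValueError):
            count_stack(FrameStack(np.zeros((1, 16, 16))), "WPF")

    def test_event_stream_has_classes_and_flags(self, rng):
        from lowvoltcount.synth_frames import DetectorModel, \
            generate_frame_stack
        model = DetectorModel(dims=(64, 64), bse_probability=0.8)
        stack, _ = generate_frame_stack(model, 0.01, 3, seed=6)
        _, stream = count_stack(stack, "WPF",
                                weight_profile=WeightProfile.identity())
        classes = {r.size_class for r in stream.records}
        assert "small" in classes
        flags = {r.size_class for r in stream.records if r.weight_flag}
        assert flags <= {"large"}     # only large clusters carry the bit
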