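import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racetube.densitometry import (
    DensitometryProfile,
    TimeMarkSet,
    compute_profile,
    detect_band_peaks,
    detect_time_marks,
    interpolate_over_marks,
    interpolated_band_profile,
    smooth_for_bands,
    smooth_for_marks,
)
from racetube.errors import ConfigError
from racetube.image_io import RaceTubeImage
from racetube.synthetic import SyntheticSpec, generate_pack
from racetube.tube_detection import BoundaryLine, detect_boundaries


def _profile(values, variant="raw"):
    return DensitometryProfile(np.asarray(values, dtype=float), variant, 0)


def _region(y0, y1):
    return (BoundaryLine(y0, y0, "user"), BoundaryLine(y1, y1, "user"))


class TestComputeProfile:
    def test_constant_tube(self):
        img = RaceTubeImage(np.full((400, 1160), 100, dtype=np.uint8))
        p = compute_profile(img, _region(100.0, 160.0), 0)
        assert len(p.values) == 1160
        np.testing.assert_allclose(p.values, 100.0)

    def test_half_and_half_step(self):
        px = np.full((400, 1160), 0, dtype=np.uint8)
        px[:, 580:] = 200
        p = compute_profile(RaceTubeImage(px), _region(100.0, 160.0), 0)
        np.testing.assert_allclose(p.values[:580], 0.0)
        np.testing.assert_allclose(p.values[580:], 200.0)

    def test_sinusoidal_tube_correlates_with_band_signal(self):
        # marks pushed out of frame so the trace is band + ramp only
        spec = SyntheticSpec(noise_sd=5.0, mark_offset_px=5000.0, seed=2)
        img, truth = generate_pack(spec)
        bset = detect_boundaries(img)
        p = compute_profile(img, bset.regions[0], 0)
        lam = truth.spec.true_period_h * truth.tube_growth_px_per_h[0]
        apex0 = truth.band_x[0][0]
        xs = np.arange(1160.0)
        band = np.zeros(1160)
        lo, hi = apex0 - lam / 2, truth.band_x[0][-1] + lam / 2
        m = (xs >= lo) & (xs <= hi)
        band[m] = 0.5 * (1 + np.cos(2 * np.pi * (xs[m] - apex0) / lam))
        assert np.corrcoef(p.values, band)[0, 1] > 0.9


class TestSmoothing:
    @pytest.mark.parametrize("smoother", [smooth_for_bands, smooth_for_marks])
    def test_constant_profile_unchanged(self, smoother):
        # exact up to the filter-coefficient roundoff (~1e-7 relative)
        p = smoother(_profile(np.full(600, 137.0)))
        np.testing.assert_allclose(p.values, 137.0, atol=1e-3)

    def test_quartic_reproduced_exactly_by_order4(self):
        x = np.linspace(-1, 1, 600)
        quartic = 100 + 5 * x + 8 * x**2 - 3 * x**3 + 6 * x**4
        out = smooth_for_bands(_profile(quartic)).values
        np.testing.assert_allclose(out, quartic, atol=1e-8)

    def test_cubic_reproduced_exactly_by_order8(self):
        x = np.linspace(-1, 1, 600)
        cubic = 120 + 4 * x - 2 * x**2 + x**3
        out = smooth_for_marks(_profile(cubic)).values
        np.testing.assert_allclose(out, cubic, atol=1e-3)

    def test_band_smoothing_reduces_noise(self):
        rng = np.random.default_rng(0)
        clean = 150 + 25 * np.sin(2 * np.pi * np.arange(1160) / 94)
        noisy = clean + rng.normal(0, 10, 1160)
        out = smooth_for_bands(_profile(noisy)).values
        assert np.sqrt(np.mean((out - clean) ** 2)) < np.sqrt(
            np.mean((noisy - clean) ** 2)
        )

    def test_order8_preserves_narrow_notch_better_than_order4(self):
        v = np.full(600, 200.0)
        v[300:303] -= 100.0
        deep = 200 - smooth_for_marks(_profile(v)).values.min()
        shallow = 200 - smooth_for_bands(_profile(v)).values.min()
        assert deep > 50  # simulated: order-8/window-31 keeps ~57% of depth
        assert deep > 1.5 * shallow
        assert int(np.argmin(smooth_for_marks(_profile(v)).values)) == 301

    def test_window_not_larger_than_order_rejected(self):
        with pytest.raises(ConfigError):
            smooth_for_bands(_profile(np.arange(100.0)), window=3, order=4)


class TestDetectTimeMarks:
    def test_constant_profile_has_no_marks(self):
        assert len(detect_time_marks(_profile(np.full(1160, 150.0)))) == 0

    def test_single_deep_notch_found_at_centre(self):
        v = np.full(1160, 180.0)
        v[498:503] = 40.0
        marks = detect_time_marks(_profile(v, "mark_smoothed"))
        assert list(marks.x_positions) == [500.0]

    def test_synthetic_marks_recovered_not_band_troughs(self, noiseless_pack):
        img, truth = noiseless_pack
        bset = detect_boundaries(img)
        p = compute_profile(img, bset.regions[0], 0)
        marks = detect_time_marks(smooth_for_marks(p))
        assert len(marks) == len(truth.marks_x[0])
        np.testing.assert_allclose(
            marks.x_positions, truth.marks_x[0], atol=2.0
        )
        # no detection at band troughs (midpoints between apexes)
        troughs = (truth.band_x[0][:-1] + truth.band_x[0][1:]) / 2
        for t in troughs:
            assert np.min(np.abs(marks.x_positions - t)) > 10

    def test_overrides(self):
        v = np.full(1160, 180.0)
        v[498:503] = 40.0
        marks = detect_time_marks(
            _profile(v, "mark_smoothed"), add=(700.0,), remove=(501.0,)
        )
        assert list(marks.x_positions) == [700.0]


class TestInterpolateOverMarks:
    def test_no_marks_is_identity(self):
        p = _profile(np.linspace(0, 100, 1160), "band_smoothed")
        out = interpolate_over_marks(p, TimeMarkSet(np.array([])))
        np.testing.assert_array_equal(out.values, p.values)

    def test_flat_profile_is_fixed_point(self):
        v = np.full(1160, 150.0)
        v[500] = 20.0  # a notch inside the window is bridged flat
        out = interpolate_over_marks(
            _profile(v, "band_smoothed"), TimeMarkSet(np.array([500.0]))
        )
        np.testing.assert_allclose(out.values, 150.0)

    def test_ramp_profile_is_fixed_point(self):
        ramp = np.arange(1160) / 10.0
        out = interpolate_over_marks(
            _profile(ramp, "band_smoothed"), TimeMarkSet(np.array([500.0]))
        )
        np.testing.assert_allclose(out.values, ramp, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        marks=st.lists(st.integers(13, 1146), min_size=1, max_size=8, unique=True),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_untouched_outside_exclusion_windows(self, marks, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 255, 1160)
        p = _profile(v, "band_smoothed")
        xs = np.array(sorted(marks), dtype=float)
        out = interpolate_over_marks(p, TimeMarkSet(xs), half_width=12)
        excluded = np.zeros(1160, dtype=bool)
        for x in xs:
            lo, hi = int(x) - 12, int(x) + 12
            excluded[max(lo, 0) : hi + 1] = True
        np.testing.assert_array_equal(out.values[~excluded], v[~excluded])

    def test_window_clipped_at_edge_holds_anchor(self):
        v = np.full(100, 80.0)
        v[:5] = 10.0
        out = interpolate_over_marks(
            _profile(v, "band_smoothed"), TimeMarkSet(np.array([2.0])),
            half_width=12,
        )
        np.testing.assert_allclose(out.values, 80.0)


class TestDetectBandPeaks:
    def test_constant_profile_has_no_peaks(self):
        assert len(detect_band_peaks(_profile(np.full(1160, 90.0)))) == 0

    def test_sinusoid_peaks_at_analytic_maxima(self):
        x = np.arange(940)
        v = 150 + 30 * np.cos(2 * np.pi * (x - 47) / 94)  # apexes at 47+94k
        peaks = detect_band_peaks(_profile(v, "interpolated"))
        expected = 47 + 94 * np.arange(10)
        assert len(peaks) == 10
        np.testing.assert_allclose(peaks.x_positions, expected, atol=1.0)

    def test_narrow_spike_rejected_by_width(self):
        x = np.arange(940)
        v = 150 + 30 * np.cos(2 * np.pi * (x - 47) / 94)
        v[564:566] += 60  # 2 px wide artifact at a band trough
        peaks = detect_band_peaks(_profile(v, "interpolated"))
        assert len(peaks) == 10
        assert np.min(np.abs(peaks.x_positions - 564)) > 10


def test_band_count_recovered_through_full_densitometry(noisy_pack):
    img, truth = noisy_pack
    bset = detect_boundaries(img)
    for k, region in enumerate(bset.regions):
        raw = compute_profile(img, region, k)
        marks = detect_time_marks(smooth_for_marks(raw))
        interp = interpolated_band_profile(raw, marks)
        peaks = detect_band_peaks(interp)
        assert len(peaks) == len(truth.band_x[k])
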