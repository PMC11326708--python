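import numpy as np
import pytest
from scipy.signal import lombscargle as scipy_lombscargle

from racetube.calibration import fit_time_calibration
from racetube.densitometry import BandPeakSet, DensitometryProfile, TimeMarkSet
from racetube.errors import (
    DegenerateSeriesError,
    InsufficientPeaksError,
    WindowError,
)
from racetube.periods import (
    all_periods,
    cwt_analysis,
    lomb_scargle_power,
    period_linear_regression,
    periodogram_lomb_scargle,
    periodogram_sokolove_bushell,
    slice_window,
    sokolove_bushell_power,
)

# ---------------------------------------------------------------------------
# independent oracles: literal loop transcriptions of the two periodogram
# definitions, kept deliberately naive
# ---------------------------------------------------------------------------


def sb_oracle(x, P):
    N = len(x)
    xbar = sum(x) / N
    K = N // P
    col_means = [sum(x[r * P + h] for r in range(K)) / K for h in range(P)]
    num = K * sum((m - xbar) ** 2 for m in col_means)
    den = sum((xi - xbar) ** 2 for xi in x) / (N - 1)
    return num / den


def ls_oracle(x, t, f):
    x = [xi - sum(x) / len(x) for xi in x]
    w = 2 * np.pi * f
    tau = np.arctan2(
        sum(np.sin(2 * w * tj) for tj in t), sum(np.cos(2 * w * tj) for tj in t)
    ) / (2 * w)
    c = sum(xj * np.cos(w * (tj - tau)) for xj, tj in zip(x, t)) ** 2 / sum(
        np.cos(w * (tj - tau)) ** 2 for tj in t
    )
    s = sum(xj * np.sin(w * (tj - tau)) for xj, tj in zip(x, t)) ** 2 / sum(
        np.sin(w * (tj - tau)) ** 2 for tj in t
    )
    return 0.5 * (c + s)


def _cal(hours_per_px=0.24, n=1101, spacing=100):
    xs = np.arange(0, n, spacing, dtype=float)
    return fit_time_calibration(TimeMarkSet(xs, xs * hours_per_px))


def _profile(values, x_offset=0):
    return DensitometryProfile(
        np.asarray(values, dtype=float), "interpolated", 0, x_offset=x_offset
    )


class TestSokoloveBushell:
    def test_matches_loop_oracle_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(200, 1200))
            x = rng.normal(100, 10, n) + 20 * np.sin(
                2 * np.pi * np.arange(n) / rng.uniform(60, 150)
            )
            periods = rng.integers(20, n // 2, size=6)
            got = sokolove_bushell_power(x, periods)
            want = np.array([sb_oracle(list(x), int(P)) for P in periods])
            np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_square_wave_peak_at_true_period(self):
        x = np.where((np.arange(1128) // 47) % 2 == 0, 200.0, 100.0)  # period 94
        pg = periodogram_sokolove_bushell(_profile(x), _cal(n=1128))
        assert pg.peak_period_h == pytest.approx(94 * 0.24, abs=0.24)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            periodogram_sokolove_bushell(_profile(np.full(1101, 7.0)), _cal())

    def test_power_is_finite_and_nonnegative(self):
        rng = np.random.default_rng(3)
        pg = periodogram_sokolove_bushell(
            _profile(rng.normal(100, 5, 1101)), _cal()
        )
        assert np.all(np.isfinite(pg.power)) and np.all(pg.power >= 0)


class TestLombScargle:
    def test_matches_loop_oracle_and_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = int(rng.integers(200, 1200))
            x = rng.normal(50, 8, n)
            t = np.arange(n, dtype=float)
            freqs = rng.uniform(1 / 150, 1 / 20, size=5)
            got = lomb_scargle_power(x, t, freqs)
            want = np.array([ls_oracle(list(x), t, f) for f in freqs])
            np.testing.assert_allclose(got, want, rtol=1e-9)
            # scipy implements the same classical statistic
            sp = scipy_lombscargle(t, x - x.mean(), 2 * np.pi * freqs)
            np.testing.assert_allclose(got, sp, rtol=1e-6)

    def test_sinusoid_peak_at_true_period(self):
        x = np.sin(2 * np.pi * np.arange(1128) / 94.0)
        pg = periodogram_lomb_scargle(_profile(x), _cal(n=1128))
        assert pg.peak_period_h == pytest.approx(94 * 0.24, abs=0.1)

    def test_unit_sinusoid_power_is_quarter_n(self):
        n = 1128
        x = np.sin(2 * np.pi * np.arange(n) / 94.0)
        power = lomb_scargle_power(x, np.arange(n, dtype=float), np.array([1 / 94.0]))
        assert power[0] == pytest.approx(n / 4, rel=0.05)

    def test_zero_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            periodogram_lomb_scargle(_profile(np.zeros(1101)), _cal())


class TestCWT:
    def test_stationary_sinusoid_period_and_flat_slope(self):
        t = np.arange(1101)
        p = _profile(100 + 20 * np.sin(2 * np.pi * t / 94.0))
        res = cwt_analysis(p, _cal())
        assert res.period_h == pytest.approx(94 * 0.24, rel=0.05)
        assert abs(res.slope) < 0.02
        assert np.all(
            res.amplitude.max(axis=0)[res.accepted]
            > 0.75 * res.amplitude.max()
        )

    def test_chirp_yields_positive_slope(self):
        t = np.arange(1101)
        inst = 80 + 30 * t / 1100  # period drifts 80 -> 110 px
        p = _profile(100 + 20 * np.sin(2 * np.pi * np.cumsum(1.0 / inst)))
        assert cwt_analysis(p, _cal()).slope > 0

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            cwt_analysis(_profile(np.full(1101, 9.0)), _cal())


class TestLinearRegression:
    @pytest.mark.parametrize(
        "peaks,hpp,expected",
        [
            ([150.0, 243.75], 0.24, 22.5),
            ([100.0, 200.0, 300.0], 0.225, 22.5),
        ],
    )
    def test_forced_arithmetic(self, peaks, hpp, expected):
        xs = np.arange(0, 1101, 100, dtype=float)
        cal = fit_time_calibration(TimeMarkSet(xs, xs * hpp))
        est = period_linear_regression(BandPeakSet(np.array(peaks)), cal)
        assert est.period_h == pytest.approx(expected)

    def test_single_peak_rejected(self):
        with pytest.raises(InsufficientPeaksError):
            period_linear_regression(BandPeakSet(np.array([100.0])), _cal())


class TestSliceWindow:
    def _setup(self):
        p = _profile(np.arange(1160.0))
        marks = TimeMarkSet(
            np.array([100.0, 200.0, 300.0]), np.array([0.0, 24.0, 48.0])
        )
        return p, marks

    def test_full_window_is_identity_span(self):
        p, marks = self._setup()
        sub, sm = slice_window(p, marks, 0, 2)
        assert sub.x_offset == 100 and len(sub.values) == 201
        assert len(sm) == 3

    def test_single_interval(self):
        p, marks = self._setup()
        sub, sm = slice_window(p, marks, 0, 1)
        np.testing.assert_array_equal(sub.values, np.arange(100.0, 201.0))
        assert list(sm.x_positions) == [100.0, 200.0]

    @pytest.mark.parametrize("i,j", [(1, 1), (2, 0), (0, 5)])
    def test_bad_windows_rejected(self, i, j):
        p, marks = self._setup()
        with pytest.raises(WindowError):
            slice_window(p, marks, i, j)


class TestAllPeriods:
    def test_noiseless_pack_all_methods_agree(self, noiseless_records):
        for rec in noiseless_records:
            ests = rec.periods()
            values = [e.period_h for e in ests.values()]
            assert all(e.ok for e in ests.values())
            assert all(22.0 <= v <= 23.0 for v in values)
            assert max(values) - min(values) <= 0.5

    def test_single_band_peak_fails_only_lr(self, noiseless_records):
        rec = noiseless_records[0]
        ests = all_periods(
            rec.interpolated_profile(),
            rec.marks(),
            BandPeakSet(np.array([rec.band_x[3]])),  # one peak in the window
        )
        assert not ests["linear_regression"].ok
        assert ests["sokolove_bushell"].ok
        assert ests["lomb_scargle"].ok
        assert ests["cwt"].ok

    def test_deterministic(self, noiseless_records):
        rec = noiseless_records[0]
        a = rec.periods()
        b = rec.periods()
        for m in a:
            assert a[m].period_h == b[m].period_h


def test_pixel_hour_commutation():
    """Peak in pixels converts to the same hour value for any calibration."""
    rng = np.random.default_rng(4)
    x = rng.normal(0, 3, 1101) + 15 * np.sin(2 * np.pi * np.arange(1101) / 94.0)
    p = _profile(x + 120)
    for hpp in (0.20, 0.24, 0.30):
        cal = _cal(hours_per_px=hpp)
        sb = periodogram_sokolove_bushell(p, cal)
        ls = periodogram_lomb_scargle(p, cal)
        assert sb.peak_period_h / hpp == pytest.approx(94, abs=1.0)
        assert ls.peak_period_h / hpp == pytest.approx(94, abs=1.0)
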