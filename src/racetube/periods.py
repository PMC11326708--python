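"""Circadian period estimation from interpolated densitometry.

Four estimators are provided, all operating on a selected window of the
interpolated trace (between any two time marks) with the pixel axis mapped
to hours via the time-mark calibration:

* **Linear regression** — period = mean spacing between consecutive
  conidial band peaks, in pixels, times hours-per-pixel.
* **Sokolove-Bushell chi-squared periodogram** — for each candidate period
  ``P`` (integer pixels) the series is folded into ``K = floor(N/P)`` rows
  of length ``P`` and the statistic

      Q_P = K * sum_h (col_mean_h - grand_mean)^2
            -----------------------------------------
            (1/(N-1)) * sum_i (X_i - grand_mean)^2

  is evaluated (column/grand means and variance over the full series).
  This is the normalization as commonly printed in circadian software;
  it differs from some textbook variants by constant factors that do not
  move the argmax.
* **Lomb-Scargle periodogram** — the classical normalized form with the
  phase offset tau defined by ``tan(2*w*tau) = sum sin(2*w*t) / sum
  cos(2*w*t)``, evaluated on an oversampled frequency grid.  For a unit
  sinusoid the power at the true frequency approaches N/4.
* **Continuous wavelet transform** — complex Morlet CWT over log-spaced
  scales spanning the search band; the per-time ridge (period of maximal
  amplitude) is averaged over the time points whose ridge amplitude
  exceeds 75% of the global maximum.  The slope of the best-fit line
  through the accepted ridge (hours of period per hour of elapsed time)
  diagnoses period drift.

The search band defaults to 14-40 h: an unrestricted argmax can land on
harmonics or the residual growth trend, while the band brackets the
free-running circadian range with wide margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import detrend as _linear_detrend

from .calibration import CalibrationModel, fit_time_calibration
from .densitometry import BandPeakSet, DensitometryProfile, TimeMarkSet
from .errors import (
    DegenerateSeriesError,
    InsufficientPeaksError,
    WindowError,
)

DEFAULT_BAND_H = (14.0, 40.0)
CWT_WAVELET = "cmor2.5-1.0"  # complex Morlet, centre frequency 1.0
CWT_N_SCALES = 100
CWT_RIDGE_FRACTION = 0.75
LS_OVERSAMPLE = 16

METHODS = ("linear_regression", "sokolove_bushell", "lomb_scargle", "cwt")


@dataclass
class Periodogram:
    """Power-versus-period spectrum with its in-band peak."""

    periods_h: np.ndarray
    power: np.ndarray
    method: str
    peak_period_h: float


@dataclass
class CWTResult:
    """Continuous wavelet transform of one tube window.

    ``amplitude`` is a (period x time) magnitude matrix; ``ridge_periods_h``
    is the per-time period of maximal amplitude; ``accepted`` flags the time
    points whose ridge amplitude exceeds the 75%-of-maximum criterion.
    """

    amplitude: np.ndarray
    times_h: np.ndarray
    periods_h: np.ndarray
    ridge_periods_h: np.ndarray
    accepted: np.ndarray
    period_h: float
    slope: float


@dataclass
class PeriodEstimate:
    """One period estimate; ``error`` is set when the method failed."""

    method: str
    period_h: float
    window: tuple[int, int] = (0, -1)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def slice_window(
    profile: DensitometryProfile,
    marks: TimeMarkSet,
    i: int,
    j: int,
) -> tuple[DensitometryProfile, TimeMarkSet]:
    """Restrict a profile and its marks to the span between marks i and j."""
    if not (0 <= i < j < len(marks)):
        raise WindowError(f"invalid mark window ({i}, {j}) for {len(marks)} marks")
    x_lo = int(round(marks.x_positions[i]))
    x_hi = int(round(marks.x_positions[j]))
    sub = profile.slice(x_lo, x_hi)
    sel = (marks.x_positions >= x_lo) & (marks.x_positions <= x_hi)
    times = marks.times_h[sel] if marks.times_h is not None else None
    return sub, TimeMarkSet(marks.x_positions[sel], times)


def period_linear_regression(
    bands: BandPeakSet,
    cal: CalibrationModel,
    window: tuple[int, int] = (0, -1),
) -> PeriodEstimate:
    """Period from the mean spacing of consecutive conidial band peaks."""
    if len(bands) < 2:
        raise InsufficientPeaksError(
            f"{len(bands)} band peak(s); need at least 2 for a period"
        )
    mean_spacing_px = float(np.mean(np.diff(bands.x_positions)))
    return PeriodEstimate(
        "linear_regression", mean_spacing_px * cal.hours_per_px, window
    )


def _prepare_series(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise DegenerateSeriesError("constant series has no period")
    return x


def _band_px(band_h, cal: CalibrationModel, n: int) -> tuple[int, int]:
    lo_h, hi_h = band_h
    p_min = max(2, int(np.ceil(lo_h / cal.hours_per_px)))
    p_max = min(int(np.floor(hi_h / cal.hours_per_px)), n // 2)
    if p_max < p_min:
        raise WindowError(
            f"window of {n} px too short for search band {band_h} h"
        )
    return p_min, p_max


def sokolove_bushell_power(values: np.ndarray, periods_px: np.ndarray) -> np.ndarray:
    """Chi-squared periodogram power at each candidate period (pixels).

    Vectorized over the folded columns for each period; the trailing
    ``N mod P`` samples are discarded so every fold has K complete rows.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    grand = x.mean()
    denom = np.sum((x - grand) ** 2) / (n - 1)
    if denom == 0:
        raise DegenerateSeriesError("zero-variance series")
    q = np.empty(len(periods_px))
    for k, p in enumerate(periods_px):
        p = int(p)
        rows = n // p
        folded = x[: rows * p].reshape(rows, p)
        col_means = folded.mean(axis=0)
        q[k] = rows * np.sum((col_means - grand) ** 2) / denom
    return q


def periodogram_sokolove_bushell(
    profile: DensitometryProfile,
    cal: CalibrationModel,
    band_h: tuple[float, float] = DEFAULT_BAND_H,
) -> Periodogram:
    """Sokolove-Bushell chi-squared periodogram over the circadian band."""
    x = np.asarray(profile.values, dtype=float)
    if np.allclose(x, x.mean()):
        raise DegenerateSeriesError("constant series has no period")
    p_min, p_max = _band_px(band_h, cal, len(x))
    periods_px = np.arange(p_min, p_max + 1)
    power = sokolove_bushell_power(x, periods_px)
    periods_h = periods_px * cal.hours_per_px
    peak = float(periods_h[int(np.argmax(power))])
    return Periodogram(periods_h, power, "sokolove_bushell", peak)


def lomb_scargle_power(
    values: np.ndarray, times: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Classical Lomb-Scargle power at each frequency (cycles per time unit).

    The input series is mean-centred internally; the tau phase offset makes
    the statistic invariant to time-origin shifts.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    t = np.asarray(times, dtype=float)
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float)[:, None]  # (F, 1)
    two_wt = 2.0 * w * t[None, :]
    tau = np.arctan2(np.sin(two_wt).sum(axis=1), np.cos(two_wt).sum(axis=1)) / (
        2.0 * w[:, 0]
    )
    arg = w * (t[None, :] - tau[:, None])
    c, s = np.cos(arg), np.sin(arg)
    xc = (x[None, :] * c).sum(axis=1)
    xs = (x[None, :] * s).sum(axis=1)
    cc = (c**2).sum(axis=1)
    ss = (s**2).sum(axis=1)
    return 0.5 * (xc**2 / cc + xs**2 / ss)


def periodogram_lomb_scargle(
    profile: DensitometryProfile,
    cal: CalibrationModel,
    band_h: tuple[float, float] = DEFAULT_BAND_H,
    oversample: int = LS_OVERSAMPLE,
) -> Periodogram:
    """Lomb-Scargle periodogram over the circadian band.

    The frequency grid spans the band with spacing ``1 / (oversample * N)``
    so the peak period is resolved well below the band-to-band spacing.
    """
    x = _prepare_series(profile.values)
    n = len(x)
    if n < 8:
        raise WindowError("need at least 8 samples for a Lomb-Scargle spectrum")
    p_min, p_max = _band_px(band_h, cal, n)
    df = 1.0 / (oversample * n)
    freqs = np.arange(1.0 / p_max, 1.0 / p_min + df, df)
    t = np.arange(n, dtype=float)
    power = lomb_scargle_power(x, t, freqs)
    periods_h = (1.0 / freqs) * cal.hours_per_px
    peak = float(periods_h[int(np.argmax(power))])
    return Periodogram(periods_h, power, "lomb_scargle", peak)


def cwt_analysis(
    profile: DensitometryProfile,
    cal: CalibrationModel,
    band_h: tuple[float, float] = DEFAULT_BAND_H,
    wavelet: str = CWT_WAVELET,
    n_scales: int = CWT_N_SCALES,
    detrend: bool = True,
    ridge_fraction: float = CWT_RIDGE_FRACTION,
) -> CWTResult:
    """Continuous wavelet transform ridge analysis of one tube window.

    The trace is linearly detrended by default (the growth-front brightness
    gradient otherwise dominates the low-frequency amplitudes), transformed
    with a complex Morlet wavelet over ``n_scales`` log-spaced scales, and
    summarized by the mean ridge period over the accepted time points.
    """
    x = np.asarray(profile.values, dtype=float)
    if np.allclose(x, x.mean()):
        raise DegenerateSeriesError("constant series has no wavelet spectrum")
    x = _linear_detrend(x) if detrend else x - x.mean()
    n = len(x)
    lo_px = band_h[0] / cal.hours_per_px
    hi_px = min(band_h[1] / cal.hours_per_px, n / 4.0)
    if hi_px <= lo_px:
        raise WindowError("window too short for the requested CWT band")
    periods_px = np.geomspace(lo_px, hi_px, n_scales)
    wav = pywt.ContinuousWavelet(wavelet)
    scales = periods_px * pywt.central_frequency(wav)
    # reflection padding by one maximum period damps edge distortion of the
    # ridge; the padded margins are cropped before ridge extraction
    pad = int(np.ceil(hi_px))
    xp = np.pad(x, pad, mode="reflect")
    coef, _ = pywt.cwt(xp, scales, wav, sampling_period=1.0)
    amp = np.abs(coef)[:, pad : pad + n]  # (n_scales, n)

    col_max = amp.max(axis=0)
    ridge_idx = amp.argmax(axis=0)
    ridge_h = periods_px[ridge_idx] * cal.hours_per_px
    accepted = col_max > ridge_fraction * amp.max()
    # cone-of-influence mask: within one maximum search period of either
    # window end the ridge reflects truncated signal content, not rhythm
    coi = min(int(np.ceil(hi_px)), n // 3)
    accepted[:coi] = False
    accepted[n - coi :] = False
    if not accepted.any():  # window too short for the mask; fall back
        accepted = col_max > ridge_fraction * amp.max()
    period_h = float(ridge_h[accepted].mean())
    times_h = (profile.x_offset + np.arange(n)) * cal.hours_per_px
    if accepted.sum() >= 2:
        slope = float(np.polyfit(times_h[accepted], ridge_h[accepted], 1)[0])
    else:
        warnings.warn("fewer than 2 accepted ridge points; CWT slope set to 0")
        slope = 0.0
    return CWTResult(
        amplitude=amp,
        times_h=times_h,
        periods_h=periods_px * cal.hours_per_px,
        ridge_periods_h=ridge_h,
        accepted=accepted,
        period_h=period_h,
        slope=slope,
    )


def all_periods(
    interpolated: DensitometryProfile,
    marks: TimeMarkSet,
    bands: BandPeakSet,
    window: tuple[int, int] | None = None,
    band_h: tuple[float, float] = DEFAULT_BAND_H,
    least_squares_calibration: bool = False,
) -> dict[str, PeriodEstimate]:
    """All four period estimates on the same mark-to-mark window.

    Each method may fail independently (e.g. too few band peaks for linear
    regression); failures are returned as estimates with ``error`` set and
    ``period_h = nan`` rather than aborting the others.
    """
    if window is None:
        window = (0, len(marks) - 1)
    i, j = window
    if j < 0:
        j += len(marks)
    sub, sub_marks = slice_window(interpolated, marks, i, j)
    cal = fit_time_calibration(sub_marks, least_squares=least_squares_calibration)
    in_win = (bands.x_positions >= sub.x_offset) & (
        bands.x_positions <= sub.x_offset + len(sub.values) - 1
    )
    sub_bands = BandPeakSet(bands.x_positions[in_win])

    out: dict[str, PeriodEstimate] = {}

    def attempt(method, fn):
        try:
            out[method] = fn()
        except Exception as exc:  # noqa: BLE001 - every failure is per-method
            out[method] = PeriodEstimate(method, float("nan"), (i, j), str(exc))

    attempt(
        "linear_regression",
        lambda: period_linear_regression(sub_bands, cal, (i, j)),
    )
    attempt(
        "sokolove_bushell",
        lambda: PeriodEstimate(
            "sokolove_bushell",
            periodogram_sokolove_bushell(sub, cal, band_h).peak_period_h,
            (i, j),
        ),
    )
    attempt(
        "lomb_scargle",
        lambda: PeriodEstimate(
            "lomb_scargle",
            periodogram_lomb_scargle(sub, cal, band_h).peak_period_h,
            (i, j),
        ),
    )
    attempt(
        "cwt",
        lambda: PeriodEstimate(
            "cwt", cwt_analysis(sub, cal, band_h).period_h, (i, j)
        ),
    )
    return out
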