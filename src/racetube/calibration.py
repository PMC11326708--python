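"""Pixel <-> hour <-> millimetre calibration from time marks.

The daily pen marks anchor pixel position to clock time.  Growth is treated
as piecewise linear between marks: the growth rate in pixels per hour is
the mean over consecutive mark pairs of ``dx / dt`` (a least-squares slope
through all marks is available as an alternative).  An optional physical
measurement of the distance between the first and last marks converts the
rate to millimetres per hour; without it the growth rate is simply not
applicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densitometry import TimeMarkSet
from .errors import CalibrationError


@dataclass
class CalibrationModel:
    """Pixel-to-hour (and optionally pixel-to-millimetre) conversion."""

    hours_per_px: float
    px_per_hour: float
    marks: TimeMarkSet
    mm_per_px: float | None = None

    def px_to_hours(self, dx_px) -> np.ndarray | float:
        return np.asarray(dx_px, dtype=float) * self.hours_per_px


def _rates(marks: TimeMarkSet) -> np.ndarray:
    if marks.times_h is None:
        raise CalibrationError("marks carry no clock times")
    if len(marks) < 2:
        raise CalibrationError("at least two time marks are required")
    dx = np.diff(marks.x_positions)
    dt = np.diff(marks.times_h)
    if np.any(dx <= 0) or np.any(dt <= 0):
        raise CalibrationError("mark positions/times must be strictly increasing")
    return dx / dt


def fit_time_calibration(
    marks: TimeMarkSet, least_squares: bool = False
) -> CalibrationModel:
    """Fit the pixels-per-hour growth rate from time marks.

    By default the rate is the mean of the per-interval rates ``dx/dt``.
    With ``least_squares=True`` it is the slope of the ordinary
    least-squares line of mark position against mark time.
    """
    rates = _rates(marks)  # validates ordering and count
    if least_squares:
        px_per_hour = float(
            np.polyfit(marks.times_h, marks.x_positions, 1)[0]
        )
    else:
        px_per_hour = float(np.mean(rates))
    if px_per_hour <= 0:
        raise CalibrationError("non-positive growth rate")
    return CalibrationModel(
        hours_per_px=1.0 / px_per_hour, px_per_hour=px_per_hour, marks=marks
    )


def growth_rate(
    marks: TimeMarkSet,
    measured_mm: float | None = None,
    least_squares: bool = False,
) -> float | None:
    """Growth rate in mm/h, or ``None`` (N/A) without a physical measurement.

    ``measured_mm`` is the measured distance between the first and last time
    marks; it fixes the mm-per-pixel scale, which multiplied by the mean
    pixels-per-hour rate gives mm per hour.
    """
    cal = fit_time_calibration(marks, least_squares=least_squares)
    if measured_mm is None:
        return None
    if measured_mm <= 0:
        raise CalibrationError("measured distance must be positive")
    span_px = float(marks.x_positions[-1] - marks.x_positions[0])
    mm_per_px = measured_mm / span_px
    return cal.px_per_hour * mm_per_px
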