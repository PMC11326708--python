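"""Per-tube densitometry: brightness traces, smoothing, and feature finding.

Each tube region is collapsed to a one-dimensional trace of mean brightness
per image column (the *raw densitometry*).  Two Savitzky-Golay variants are
derived from it:

* ``band_smoothed`` — order-4 polynomial, wide window; suppresses pixel
  texture while keeping the broad conidial band peaks.
* ``mark_smoothed`` — order-8 polynomial, 31 px window; the high order
  preserves the sharp, narrow notches left by the daily pen marks so they
  can be located precisely.

Pen marks are detected as extreme local minima of the mark-smoothed trace
that satisfy both a prominence criterion and a steep-flank criterion (the
flank slope is what separates ink strokes from the gentle troughs between
conidial bands).  Detected marks are then excised from the band-smoothed
trace by bridging a fixed window around each mark with a straight line,
and conidial band peaks are found on the resulting interpolated trace as
local maxima of sufficient width and prominence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ConfigError
from .image_io import RaceTubeImage
from .tube_detection import BoundaryLine

BAND_SMOOTH_WINDOW = 45   # px; ~half a band at typical scale
BAND_SMOOTH_ORDER = 4
MARK_SMOOTH_WINDOW = 31   # px; nominal 30, rounded up to the next odd width
MARK_SMOOTH_ORDER = 8
MARK_PROMINENCE = 15.0    # brightness units
MARK_MIN_SLOPE = 3.0      # brightness units per px, max flank slope
MARK_MIN_DISTANCE = 20    # px; suppresses smoothing-ringing sidelobe minima
MARK_EDGE_EXCLUSION = 15  # px; half a smoothing window -- edge fits are
                          # unreliable and a mark there is unusable anyway
MARK_SLOPE_WINDOW = 5     # px on each side over which flank slope is taken
MARK_HALF_WIDTH = 12      # px excised on each side of a detected mark
BAND_MIN_WIDTH = 10.0     # px
BAND_PROMINENCE = 8.0     # brightness units
BAND_MIN_DISTANCE = 30    # px; bands cannot repeat faster than the shortest
                          # circadian period (~58 px at typical growth rates)
OVERRIDE_TOLERANCE = 10.0  # px; radius for matching remove-overrides


@dataclass
class DensitometryProfile:
    """A 1-D brightness trace for one tube.

    ``values[i]`` is the mean brightness of image column ``x_offset + i``
    restricted to the rows of the tube region.  ``variant`` tracks the
    processing stage: raw, band_smoothed, mark_smoothed, or interpolated.
    """

    values: np.ndarray
    variant: str
    tube_index: int
    x_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")

    @property
    def x(self) -> np.ndarray:
        """Image-column coordinates of the trace."""
        return self.x_offset + np.arange(len(self.values))

    def slice(self, x_lo: int, x_hi: int) -> "DensitometryProfile":
        """Sub-profile over image columns ``[x_lo, x_hi]`` inclusive."""
        i0 = x_lo - self.x_offset
        i1 = x_hi - self.x_offset
        if i0 < 0 or i1 >= len(self.values) or i0 > i1:
            raise ValueError("slice outside profile")
        return replace(self, values=self.values[i0 : i1 + 1], x_offset=x_lo)


@dataclass
class TimeMarkSet:
    """Pen-mark pixel columns, optionally paired with clock times in hours."""

    x_positions: np.ndarray
    times_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_positions = np.asarray(self.x_positions, dtype=float)
        if np.any(np.diff(self.x_positions) <= 0):
            raise ValueError("mark x positions must be strictly increasing")
        if self.times_h is not None:
            self.times_h = np.asarray(self.times_h, dtype=float)
            if len(self.times_h) != len(self.x_positions):
                raise ValueError("times and positions must have equal length")
            if np.any(np.diff(self.times_h) <= 0):
                raise ValueError("mark times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x_positions)

    def with_times(self, times_h) -> "TimeMarkSet":
        return TimeMarkSet(self.x_positions.copy(), np.asarray(times_h, dtype=float))

    def with_interval(self, interval_h: float) -> "TimeMarkSet":
        """Assign clock times 0, interval, 2*interval, ... to the marks."""
        return self.with_times(interval_h * np.arange(len(self.x_positions)))


@dataclass
class BandPeakSet:
    """Pixel columns of conidial-band density maxima (strictly increasing)."""

    x_positions: np.ndarray

    def __post_init__(self) -> None:
        self.x_positions = np.asarray(self.x_positions, dtype=float)
        if np.any(np.diff(self.x_positions) <= 0):
            raise ValueError("band peak positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x_positions)


def compute_profile(
    img: RaceTubeImage,
    region: tuple[BoundaryLine, BoundaryLine],
    tube_index: int,
) -> DensitometryProfile:
    """Raw densitometry of one tube region.

    For every column the rows strictly between the (possibly sloped) top and
    bottom boundary lines are averaged.
    """
    top, bottom = region
    pixels = img.pixels.astype(float)
    height, width = pixels.shape
    values = np.empty(width)
    xs = np.arange(width)
    y_top = np.array([top.y_at(x, width) for x in (0, width - 1)])
    y_bot = np.array([bottom.y_at(x, width) for x in (0, width - 1)])
    tops = np.interp(xs, [0, width - 1], y_top)
    bots = np.interp(xs, [0, width - 1], y_bot)
    for x in xs:
        r0 = int(np.floor(tops[x])) + 1
        r1 = int(np.ceil(bots[x])) - 1
        r0, r1 = max(r0, 0), min(r1, height - 1)
        if r1 < r0:
            raise ValueError(f"empty tube region at column {x}")
        values[x] = pixels[r0 : r1 + 1, x].mean()
    return DensitometryProfile(values, "raw", tube_index)


def _savgol(p: DensitometryProfile, window: int, order: int, variant: str):
    if window % 2 == 0:
        window += 1
    if window <= order:
        raise ConfigError(f"smoothing window {window} must exceed order {order}")
    if len(p.values) < window:
        raise ConfigError("profile shorter than smoothing window")
    out = savgol_filter(p.values, window_length=window, polyorder=order)
    return replace(p, values=out, variant=variant)


def smooth_for_bands(
    p: DensitometryProfile,
    window: int = BAND_SMOOTH_WINDOW,
    order: int = BAND_SMOOTH_ORDER,
) -> DensitometryProfile:
    """Order-4 Savitzky-Golay smoothing tuned for conidial band detection."""
    return _savgol(p, window, order, "band_smoothed")


def smooth_for_marks(
    p: DensitometryProfile,
    window: int = MARK_SMOOTH_WINDOW,
    order: int = MARK_SMOOTH_ORDER,
) -> DensitometryProfile:
    """Order-8 Savitzky-Golay smoothing tuned for pen-mark detection."""
    return _savgol(p, window, order, "mark_smoothed")


def _max_flank_slope(v: np.ndarray, i: int, window: int) -> float:
    """Steeper of the two sustained flank slopes at the minimum ``i``.

    Sustained slope = mean rise per pixel from the minimum to the flank
    window edge.  Single-step differences would be dominated by residual
    pixel noise; an ink notch rises tens of brightness units over a few
    pixels, a conidial band trough only ~1 unit/px.
    """
    slopes = []
    left = min(window, i)
    if left > 0:
        slopes.append(float(v[i - left] - v[i]) / left)
    right = min(window, len(v) - 1 - i)
    if right > 0:
        slopes.append(float(v[i + right] - v[i]) / right)
    return max(slopes) if slopes else 0.0


def detect_time_marks(
    p: DensitometryProfile,
    prominence: float = MARK_PROMINENCE,
    min_slope: float = MARK_MIN_SLOPE,
    slope_window: int = MARK_SLOPE_WINDOW,
    min_distance: int = MARK_MIN_DISTANCE,
    edge_exclusion: int = MARK_EDGE_EXCLUSION,
    add: tuple[float, ...] = (),
    remove: tuple[float, ...] = (),
) -> TimeMarkSet:
    """Locate pen-mark minima on the mark-smoothed trace.

    A local minimum qualifies when its prominence is at least ``prominence``
    AND its steepest flank is at least ``min_slope`` brightness units per
    pixel.  Minima closer than ``min_distance`` px are resolved in favour of
    the deeper one: a high-order smoothing filter rings around a deep narrow
    notch, and the sidelobe minima would otherwise register as extra marks.
    User overrides are applied after detection: ``add`` inserts mark columns
    verbatim, ``remove`` deletes the nearest detected mark within
    :data:`OVERRIDE_TOLERANCE` px.
    """
    v = p.values
    idx, _ = find_peaks(-v, prominence=prominence, distance=min_distance)
    keep = [
        i
        for i in idx
        if edge_exclusion <= i < len(v) - edge_exclusion
        and _max_flank_slope(v, i, slope_window) >= min_slope
    ]
    xs = [float(p.x_offset + i) for i in keep]
    for x in remove:
        if not xs:
            break
        d = [abs(q - x) for q in xs]
        j = int(np.argmin(d))
        if d[j] <= OVERRIDE_TOLERANCE:
            xs.pop(j)
    xs.extend(float(x) for x in add)
    return TimeMarkSet(np.array(sorted(set(xs))))


def interpolate_over_marks(
    p: DensitometryProfile,
    marks: TimeMarkSet,
    half_width: int = MARK_HALF_WIDTH,
) -> DensitometryProfile:
    """Bridge each pen-mark window with a straight line.

    For a mark at column ``x`` the values in ``[x - w, x + w]`` are replaced
    by the line joining the values at ``x - w - 1`` and ``x + w + 1``.
    Overlapping windows are merged; windows clipped at a profile end hold
    the surviving anchor's value.  Values outside every window are returned
    unchanged.
    """
    v = p.values.copy()
    n = len(v)
    # merge overlapping/adjacent exclusion windows, in profile-local indices
    windows: list[list[int]] = []
    for x in np.sort(marks.x_positions):
        i = int(round(x)) - p.x_offset
        lo, hi = i - half_width, i + half_width
        if hi < 0 or lo > n - 1:
            continue
        lo, hi = max(lo, 0), min(hi, n - 1)
        if windows and lo <= windows[-1][1] + 1:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    for lo, hi in windows:
        left = lo - 1
        right = hi + 1
        if left < 0 and right > n - 1:
            continue  # window covers the whole profile; nothing to anchor on
        if left < 0:
            v[lo : hi + 1] = v[right]
        elif right > n - 1:
            v[lo : hi + 1] = v[left]
        else:
            v[lo : hi + 1] = np.linspace(v[left], v[right], hi - lo + 3)[1:-1]
    return replace(p, values=v, variant="interpolated")


def detect_band_peaks(
    p: DensitometryProfile,
    prominence: float = BAND_PROMINENCE,
    min_width: float = BAND_MIN_WIDTH,
    min_distance: int = BAND_MIN_DISTANCE,
    add: tuple[float, ...] = (),
    remove: tuple[float, ...] = (),
) -> BandPeakSet:
    """Locate conidial band maxima on the interpolated trace.

    Local maxima must have width >= ``min_width`` px (rejects residual
    noise spikes), prominence >= ``prominence`` brightness units, and be
    at least ``min_distance`` px apart (two bands cannot sit closer than
    the shortest circadian period).  Overrides behave as in
    :func:`detect_time_marks`.
    """
    idx, _ = find_peaks(
        p.values, prominence=prominence, width=min_width, distance=min_distance
    )
    xs = [float(p.x_offset + i) for i in idx]
    for x in remove:
        if not xs:
            break
        d = [abs(q - x) for q in xs]
        j = int(np.argmin(d))
        if d[j] <= OVERRIDE_TOLERANCE:
            xs.pop(j)
    xs.extend(float(x) for x in add)
    return BandPeakSet(np.array(sorted(set(xs))))


def interpolated_band_profile(
    raw: DensitometryProfile,
    marks: TimeMarkSet,
    half_width: int = MARK_HALF_WIDTH,
    window: int = BAND_SMOOTH_WINDOW,
    order: int = BAND_SMOOTH_ORDER,
) -> DensitometryProfile:
    """Band-smoothed trace with pen marks excised, ready for peak finding.

    The mark windows are bridged on the *raw* trace first, so the wide
    band-smoothing window cannot smear ink notches into the neighbouring
    signal (a smeared notch depresses the bridge anchors and fabricates
    small inter-mark bumps).  After smoothing, the windows are bridged once
    more so the final trace honours the straight-line exclusion contract.
    """
    denotched = interpolate_over_marks(raw, marks, half_width)
    smoothed = smooth_for_bands(denotched, window=window, order=order)
    return interpolate_over_marks(smoothed, marks, half_width)
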