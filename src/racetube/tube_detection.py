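"""Detection of the horizontal boundary lines separating race tubes.

Two redundant detectors are run on every pack image and the larger set of
acceptable lines wins:

1. **Canny + probabilistic Hough** — edge detection (hysteresis thresholds
   1 and 25 on the 0-255 brightness scale) followed by a progressive
   probabilistic Hough transform; long, nearly horizontal segments are
   extended to the full image width.
2. **Vertical densitometry** — mean brightness along short horizontal
   segments at every image row, sampled in a strip at the left edge and a
   strip at the centre; local minima of the two profiles are paired when
   their rows imply a line of sufficiently low slope.

The Canny route works when inter-tube margins contrast with the background;
the densitometry route is the fallback when they do not.  Tubes are the
regions between consecutive accepted lines (the image's top and bottom
edges act as implicit boundaries), numbered from the top down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

from .errors import NoTubesError
from .image_io import TARGET_HEIGHT, TARGET_WIDTH, RaceTubeImage

# Tuning defaults.  The physical constraints are loose -- boundary lines are
# long and nearly horizontal -- so these are generous:
MIN_LINE_LENGTH = 300   # px; only inter-tube margins produce lines this long
MAX_SLOPE = 5           # px of rise across the full 1160 px width
MIN_SEPARATION = 20     # px; accepted lines closer than this are duplicates
MIN_TUBE_HEIGHT = 15    # px; thinner regions are slivers, not tubes
STRIP_WIDTH = 58        # px; width of the vertical-densitometry sampling strips
DENSITY_PROMINENCE = 5.0  # brightness units for local-minima acceptance
HOUGH_LINE_GAP = 3
HOUGH_THRESHOLD = 10
CANNY_LOW = 1.0
CANNY_HIGH = 25.0
CANNY_SIGMA = 1.0
DARK_LINE_FRACTION = 0.7  # a boundary path must be darker than this fraction
                          # of the image's median brightness


@dataclass(frozen=True)
class BoundaryLine:
    """A full-width line separating two adjacent race tubes.

    ``y_left`` / ``y_right`` are the row coordinates where the line crosses
    ``x = 0`` and ``x = width - 1``; ``method`` records which detector (or
    the user, or the image edge) produced it.
    """

    y_left: float
    y_right: float
    method: str  # {"canny_hough", "vertical_density", "user", "edge"}

    @property
    def mean_y(self) -> float:
        return 0.5 * (self.y_left + self.y_right)

    def y_at(self, x: float, width: int = TARGET_WIDTH) -> float:
        """Row coordinate of the line at column ``x`` (linear in x)."""
        return self.y_left + (self.y_right - self.y_left) * x / (width - 1)


@dataclass
class TubeBoundarySet:
    """Ordered boundary lines plus the tube regions they imply."""

    lines: list[BoundaryLine]
    image_height: int = TARGET_HEIGHT
    min_tube_height: float = MIN_TUBE_HEIGHT
    regions: list[tuple[BoundaryLine, BoundaryLine]] = field(init=False)

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda l: l.mean_y)
        top = BoundaryLine(0.0, 0.0, "edge")
        bot = BoundaryLine(self.image_height - 1.0, self.image_height - 1.0, "edge")
        rail = [top, *self.lines, bot]
        self.regions = [
            (a, b)
            for a, b in zip(rail[:-1], rail[1:])
            if b.mean_y - a.mean_y >= self.min_tube_height
        ]

    @property
    def n_tubes(self) -> int:
        return len(self.regions)


def detect_canny_edges(
    img: RaceTubeImage,
    sigma: float = CANNY_SIGMA,
    low_threshold: float = CANNY_LOW,
    high_threshold: float = CANNY_HIGH,
) -> np.ndarray:
    """Binary Canny edge mask of the normalized image.

    Thresholds operate on the raw 0-255 gradient scale (the image is passed
    as float so scikit-image does not rescale it).
    """
    return canny(
        img.pixels.astype(float),
        sigma=sigma,
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )


def _merge_lines(
    candidates: list[BoundaryLine], min_separation: float
) -> list[BoundaryLine]:
    """Average together candidate lines whose mean rows fall within
    ``min_separation`` of each other (single-linkage along sorted order)."""
    if not candidates:
        return []
    candidates = sorted(candidates, key=lambda l: l.mean_y)
    merged: list[BoundaryLine] = []
    cluster = [candidates[0]]
    for line in candidates[1:]:
        if line.mean_y - cluster[-1].mean_y < min_separation:
            cluster.append(line)
        else:
            merged.append(_cluster_mean(cluster))
            cluster = [line]
    merged.append(_cluster_mean(cluster))
    return merged


def _cluster_mean(cluster: list[BoundaryLine]) -> BoundaryLine:
    yl = float(np.mean([l.y_left for l in cluster]))
    yr = float(np.mean([l.y_right for l in cluster]))
    return BoundaryLine(yl, yr, cluster[0].method)


def boundaries_from_hough(
    edges: np.ndarray,
    min_line_length: int = MIN_LINE_LENGTH,
    max_slope: float = MAX_SLOPE,
    line_gap: int = HOUGH_LINE_GAP,
    threshold: int = HOUGH_THRESHOLD,
    min_separation: float = MIN_SEPARATION,
) -> list[BoundaryLine]:
    """Boundary candidates from a progressive probabilistic Hough transform.

    Segments of length >= ``min_line_length`` whose slope, extrapolated over
    the full width, rises no more than ``max_slope`` px are extended to the
    image width; near-duplicates are merged by averaging.  The transform's
    internal sampling is seeded, so results are deterministic.
    """
    height, width = edges.shape
    segments = probabilistic_hough_line(
        edges,
        threshold=threshold,
        line_length=min_line_length,
        line_gap=line_gap,
        rng=np.random.default_rng(0),
    )
    candidates: list[BoundaryLine] = []
    for (x0, y0), (x1, y1) in segments:
        if x0 == x1:  # vertical segment, not a tube boundary
            continue
        slope = (y1 - y0) / (x1 - x0)
        y_left = y0 - slope * x0
        y_right = y0 + slope * (width - 1 - x0)
        if abs(y_right - y_left) > max_slope:
            continue
        if not (0 <= y_left < height and 0 <= y_right < height):
            continue
        candidates.append(BoundaryLine(float(y_left), float(y_right), "canny_hough"))
    return _merge_lines(candidates, min_separation)


def boundaries_from_vertical_density(
    img: RaceTubeImage,
    strip_width: int = STRIP_WIDTH,
    prominence: float = DENSITY_PROMINENCE,
    max_slope: float = MAX_SLOPE,
    pair_tolerance: float = 3.0,
    min_separation: float = MIN_SEPARATION,
) -> list[BoundaryLine]:
    """Boundary candidates from paired vertical brightness profiles.

    A left strip (columns ``[0, strip_width)``) and a centre strip (the same
    width centred at ``width // 2``) are each averaged across their columns
    to give one brightness value per row.  Local minima (prominence >=
    ``prominence``) mark dark inter-tube margins; a left minimum and a
    centre minimum are paired when their rows agree within the larger of
    ``pair_tolerance`` and the row offset implied by ``max_slope``, and the
    line through the two strip centres is extended to the full width.
    """
    pixels = img.pixels.astype(float)
    height, width = pixels.shape
    x_left_c = (strip_width - 1) / 2.0
    c0 = width // 2 - strip_width // 2
    x_center_c = c0 + (strip_width - 1) / 2.0

    left_profile = pixels[:, :strip_width].mean(axis=1)
    center_profile = pixels[:, c0 : c0 + strip_width].mean(axis=1)

    left_min, _ = find_peaks(-left_profile, prominence=prominence)
    center_min, _ = find_peaks(-center_profile, prominence=prominence)
    if len(left_min) == 0 or len(center_min) == 0:
        return []

    dx = x_center_c - x_left_c
    tol = max(pair_tolerance, max_slope * dx / (width - 1))
    lines: list[BoundaryLine] = []
    used: set[int] = set()
    for yl in left_min:
        # nearest unused centre minimum within tolerance
        best, best_d = None, np.inf
        for j, yc in enumerate(center_min):
            d = abs(float(yc) - float(yl))
            if j not in used and d < best_d:
                best, best_d = j, d
        if best is None or best_d > tol:
            continue
        used.add(best)
        yc = center_min[best]
        slope = (float(yc) - float(yl)) / dx
        y0 = float(yl) - slope * x_left_c
        y1 = float(yl) + slope * (width - 1 - x_left_c)
        if abs(y1 - y0) > max_slope:
            continue
        if 0 <= y0 < height and 0 <= y1 < height:
            lines.append(BoundaryLine(y0, y1, "vertical_density"))
    return _merge_lines(lines, min_separation)


def select_boundaries(
    canny_lines: list[BoundaryLine],
    density_lines: list[BoundaryLine],
    image_height: int = TARGET_HEIGHT,
    add: tuple[float, ...] = (),
    remove: tuple[float, ...] = (),
    remove_tolerance: float = 10.0,
    min_separation: float = MIN_SEPARATION,
    min_tube_height: float = MIN_TUBE_HEIGHT,
) -> TubeBoundarySet:
    """Pick the larger acceptable candidate set and apply user overrides.

    Ties go to the Canny/Hough set.  ``add`` rows become user lines;
    ``remove`` rows delete the nearest line within ``remove_tolerance`` px.
    Raises :class:`NoTubesError` if fewer than two tube regions remain.
    """
    chosen = canny_lines if len(canny_lines) >= len(density_lines) else density_lines
    lines = _merge_lines(list(chosen), min_separation)
    for y in remove:
        if not lines:
            break
        dists = [abs(l.mean_y - y) for l in lines]
        i = int(np.argmin(dists))
        if dists[i] <= remove_tolerance:
            lines.pop(i)
    for y in add:
        lines.append(BoundaryLine(float(y), float(y), "user"))
    lines.sort(key=lambda l: l.mean_y)
    bset = TubeBoundarySet(
        lines, image_height=image_height, min_tube_height=min_tube_height
    )
    if bset.n_tubes < 2:
        raise NoTubesError(
            f"only {bset.n_tubes} tube region(s) after boundary selection"
        )
    return bset


def line_brightness(img: RaceTubeImage, line: BoundaryLine) -> float:
    """Mean pixel brightness sampled along the line's full-width path."""
    pixels = img.pixels
    h, w = pixels.shape
    xs = np.arange(w)
    ys = np.clip(np.rint(np.interp(xs, [0, w - 1], [line.y_left, line.y_right])),
                 0, h - 1).astype(int)
    return float(pixels[ys, xs].mean())


def filter_dark_lines(
    img: RaceTubeImage,
    lines: list[BoundaryLine],
    fraction: float = DARK_LINE_FRACTION,
) -> list[BoundaryLine]:
    """Keep only candidates whose path is clearly darker than the image.

    Real inter-tube margins are dark; a pseudo-line assembled from noise
    edges runs across bright tube content and is rejected here.
    """
    cutoff = fraction * float(np.median(img.pixels))
    return [l for l in lines if line_brightness(img, l) < cutoff]


def detect_boundaries(img: RaceTubeImage, **select_kwargs) -> TubeBoundarySet:
    """Run both detectors on ``img`` and select the winning boundary set."""
    edges = detect_canny_edges(img)
    a = filter_dark_lines(img, boundaries_from_hough(edges))
    b = filter_dark_lines(img, boundaries_from_vertical_density(img))
    return select_boundaries(a, b, image_height=img.height, **select_kwargs)
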