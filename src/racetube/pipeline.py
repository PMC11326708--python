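"""End-to-end analysis: image -> boundaries -> features -> tube records.

This is the programmatic equivalent of uploading a scan: detect tube
boundaries by both methods, take the larger set, trace each tube's
densitometry, find and excise pen marks, find conidial band peaks, attach
clock times and the optional physical measurement, and bundle everything
into persistable :class:`~racetube.experiment.TubeRecord` objects.  Any
detector mistake can be corrected declaratively through
:class:`Overrides` (the replacement for click-to-edit in a GUI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import growth_rate
from .densitometry import (
    compute_profile,
    detect_band_peaks,
    detect_time_marks,
    interpolated_band_profile,
    smooth_for_marks,
)
from .errors import CalibrationError
from .experiment import TubeRecord
from .image_io import RaceTubeImage, load_image
from .tube_detection import (
    boundaries_from_hough,
    boundaries_from_vertical_density,
    detect_canny_edges,
    filter_dark_lines,
    select_boundaries,
)


@dataclass
class Overrides:
    """Declarative corrections applied after automatic detection.

    Boundary overrides are image rows; mark/peak overrides are maps from
    tube index (top-down) to pixel columns.
    """

    add_boundaries: tuple[float, ...] = ()
    remove_boundaries: tuple[float, ...] = ()
    add_marks: dict[int, tuple[float, ...]] = field(default_factory=dict)
    remove_marks: dict[int, tuple[float, ...]] = field(default_factory=dict)
    add_peaks: dict[int, tuple[float, ...]] = field(default_factory=dict)
    remove_peaks: dict[int, tuple[float, ...]] = field(default_factory=dict)


def analyze_image(
    img: RaceTubeImage | str | Path,
    pack_name: str | None = None,
    mark_times_h: list[float] | None = None,
    mark_interval_h: float | None = None,
    measured_mm: float | None = None,
    overrides: Overrides | None = None,
    orientation: str = "none",
) -> list[TubeRecord]:
    """Analyze one pack image into per-tube records.

    Clock times for the pen marks come either from ``mark_times_h`` (an
    explicit list, which must match the per-tube mark count) or from
    ``mark_interval_h`` (auto-assigns 0, interval, 2*interval, ... hours).
    ``measured_mm`` is the physical first-to-last-mark distance used for
    the growth rate; omit it to record the rate as N/A.
    """
    if isinstance(img, (str, Path)):
        img = load_image(img, orientation=orientation, pack_name=pack_name)
    if pack_name is None:
        pack_name = img.pack_name or "pack"
    if (mark_times_h is None) == (mark_interval_h is None):
        raise CalibrationError(
            "provide exactly one of mark_times_h or mark_interval_h"
        )
    ov = overrides or Overrides()

    edges = detect_canny_edges(img)
    bset = select_boundaries(
        filter_dark_lines(img, boundaries_from_hough(edges)),
        filter_dark_lines(img, boundaries_from_vertical_density(img)),
        image_height=img.height,
        add=ov.add_boundaries,
        remove=ov.remove_boundaries,
    )

    records: list[TubeRecord] = []
    for tube_index, region in enumerate(bset.regions):
        raw = compute_profile(img, region, tube_index)
        marks = detect_time_marks(
            smooth_for_marks(raw),
            add=ov.add_marks.get(tube_index, ()),
            remove=ov.remove_marks.get(tube_index, ()),
        )
        if mark_times_h is not None:
            if len(mark_times_h) != len(marks):
                raise CalibrationError(
                    f"tube {tube_index}: {len(marks)} detected marks but "
                    f"{len(mark_times_h)} mark times supplied "
                    "(use overrides to reconcile)"
                )
            marks = marks.with_times(mark_times_h)
        else:
            marks = marks.with_interval(mark_interval_h)

        interpolated = interpolated_band_profile(raw, marks)
        bands = detect_band_peaks(
            interpolated,
            add=ov.add_peaks.get(tube_index, ()),
            remove=ov.remove_peaks.get(tube_index, ()),
        )
        try:
            rate = growth_rate(marks, measured_mm)
        except CalibrationError:
            rate = None
        records.append(
            TubeRecord(
                pack_name=pack_name,
                tube_index=tube_index,
                source_image=Path(img.source_path).name if img.source_path else "",
                greyscale_image_ref=f"{pack_name}.png",
                tube_y_bounds=region,
                mark_x=[float(x) for x in marks.x_positions],
                mark_times_h=[float(t) for t in marks.times_h],
                band_x=[float(x) for x in bands.x_positions],
                growth_rate_mm_per_h=rate,
                raw_densitometry=[float(v) for v in raw.values],
            )
        )
    return records


def pack_periods(
    records: list[TubeRecord],
    window: tuple[int, int] | None = None,
    band_h: tuple[float, float] = (14.0, 40.0),
) -> dict[int, dict]:
    """Per-tube period estimates for a list of records (by tube index)."""
    return {
        rec.tube_index: rec.periods(window=window, band_h=band_h)
        for rec in records
    }


def mean_periods(
    records: list[TubeRecord],
    window: tuple[int, int] | None = None,
    band_h: tuple[float, float] = (14.0, 40.0),
) -> dict[str, float]:
    """Mean period per method across tubes (NaN-skipping)."""
    per_tube = pack_periods(records, window=window, band_h=band_h)
    out: dict[str, float] = {}
    for method in ("linear_regression", "sokolove_bushell", "lomb_scargle", "cwt"):
        vals = [
            est[method].period_h
            for est in per_tube.values()
            if est[method].ok
        ]
        out[method] = float(np.mean(vals)) if vals else float("nan")
    return out
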