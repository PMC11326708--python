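"""Synthetic race-tube pack images with exact ground truth.

The generator emulates the anatomy of a scanned six-pack: parallel
horizontal tubes separated by dark boundary lines, a bright-to-dark
growth-front brightness ramp, quasi-sinusoidal (raised-cosine) conidial
bands at a known spatial period, thin dark vertical pen marks at known
positions, and additive Gaussian pixel noise.  Every structural feature is
emitted alongside the image so detectors and period estimators can be
scored against exact ground truth.

Defaults mirror a typical wild-type-like *Neurospora* experiment: six
tubes, a free-running period of 22.5 h, growth of 4.1667 px/h (so one
93.75 px band per circadian cycle and 100 px between the daily 24 h pen
marks), moderate band contrast, and light scanner noise.

The band signal covers an integer number of full raised-cosine cycles,
trough to trough, placed entirely inside the frame: every emitted band apex
therefore has complete flanks, making the analytic peak list an exact
target for the peak detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ResolutionError
from .image_io import TARGET_HEIGHT, TARGET_WIDTH, RaceTubeImage

MIN_BAND_SPACING_PX = 20.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic race-tube pack.

    Geometry is fixed at the canonical 1160x400 frame.  ``true_period_h``
    times ``growth_px_per_h`` sets the spatial band period in pixels and
    must resolve to at least 20 px.
    """

    n_tubes: int = 6
    true_period_h: float = 22.5
    growth_px_per_h: float = 4.1667
    growth_cv: float = 0.02        # per-tube relative growth-rate variation
    phase_jitter_px: float = 16.0  # max per-tube band phase offset
    mark_interval_h: float = 24.0
    mark_jitter_px: float = 1.0
    band_contrast: float = 60.0
    background: float = 180.0
    noise_sd: float = 5.0
    boundary_darkness: float = 30.0
    tilt_px: float = 0.0
    ramp: float = 15.0            # brightness drop from x=0 to the right edge
    mark_offset_px: float = 40.0  # column of the first (t = 0 h) pen mark
    mark_depth: float = 140.0     # brightness subtracted under a pen stroke
    mark_width_px: int = 3
    boundary_thickness: int = 3
    edge_margin: int = 4          # rows between frame edge and outer boundary
    seed: int = 0

    @property
    def band_spacing_px(self) -> float:
        return self.true_period_h * self.growth_px_per_h


@dataclass
class GroundTruth:
    """Exact structural truth for one generated pack."""

    boundaries: list[tuple[float, float]]  # (y_left, y_right) per line, top-down
    marks_x: list[np.ndarray]              # per tube
    marks_t: list[np.ndarray]              # per tube, hours
    band_x: list[np.ndarray]               # per tube, analytic apex columns
    tube_growth_px_per_h: list[float] = field(default_factory=list)
    spec: SyntheticSpec = field(repr=False, default=None)

    @property
    def interior_boundaries(self) -> list[tuple[float, float]]:
        return self.boundaries[1:-1]

    @property
    def hours_per_px(self) -> float:
        return 1.0 / self.spec.growth_px_per_h


def generate_pack(spec: SyntheticSpec) -> tuple[RaceTubeImage, GroundTruth]:
    """Render a pack image and its ground truth; deterministic per seed."""
    if spec.band_spacing_px < MIN_BAND_SPACING_PX:
        raise ResolutionError(
            f"band spacing {spec.band_spacing_px:.1f} px is below the "
            f"{MIN_BAND_SPACING_PX:.0f} px resolution floor"
        )
    if spec.n_tubes < 1:
        raise ValueError("need at least one tube")
    rng = np.random.default_rng(spec.seed)
    h, w = TARGET_HEIGHT, TARGET_WIDTH
    xs = np.arange(w, dtype=float)
    canvas = np.full((h, w), spec.background, dtype=float)
    canvas -= spec.ramp * xs[None, :] / (w - 1)

    # Boundary lines: n_tubes + 1 evenly spaced rows inside the frame,
    # optionally tilted by tilt_px across the width.
    y0s = np.linspace(spec.edge_margin, h - 1 - spec.edge_margin, spec.n_tubes + 1)
    boundaries = [(float(y0), float(y0 + spec.tilt_px)) for y0 in y0s]
    tube_rows: list[tuple[np.ndarray, np.ndarray]] = []  # per-tube (top, bottom) rows at each x
    line_y = [y0 + (y1 - y0) * xs / (w - 1) for y0, y1 in boundaries]
    for k in range(spec.n_tubes):
        tube_rows.append((line_y[k], line_y[k + 1]))

    marks_x: list[np.ndarray] = []
    marks_t: list[np.ndarray] = []
    band_x: list[np.ndarray] = []
    tube_growth: list[float] = []

    half_thick = spec.boundary_thickness // 2
    half_mark = spec.mark_width_px // 2
    rows_idx = np.arange(h, dtype=float)
    for k in range(spec.n_tubes):
        # real tubes of one strain share the period but differ slightly in
        # growth rate and banding phase; both stay exact in the ground truth
        v_k = spec.growth_px_per_h * (
            1.0 + (spec.growth_cv * rng.standard_normal() if spec.growth_cv else 0.0)
        )
        v_k = max(v_k, 0.5 * spec.growth_px_per_h)
        lam = spec.true_period_h * v_k
        phase0 = lam / 2.0 + 20.0 + (
            rng.uniform(0.0, spec.phase_jitter_px) if spec.phase_jitter_px else 0.0
        )
        n_bands = int(np.floor((w - 10 - phase0 - lam / 2.0) / lam)) + 1
        apexes = phase0 + lam * np.arange(n_bands)
        band_lo = phase0 - lam / 2.0
        band_hi = apexes[-1] + lam / 2.0
        in_band = (xs >= band_lo) & (xs <= band_hi)
        band_signal = np.zeros(w)
        band_signal[in_band] = (
            spec.band_contrast
            * 0.5
            * (1.0 + np.cos(2 * np.pi * (xs[in_band] - phase0) / lam))
        )

        top, bottom = tube_rows[k]
        # tube interior mask (rows strictly between the boundary strokes)
        interior = (rows_idx[:, None] > top[None, :] + half_thick) & (
            rows_idx[:, None] < bottom[None, :] - half_thick
        )
        canvas[interior] = (canvas + band_signal[None, :])[interior]

        # pen marks: dark strokes every mark_interval_h, with placement jitter
        t_k, x_k = [], []
        t = 0.0
        while True:
            x = spec.mark_offset_px + v_k * t
            x += rng.normal(0.0, spec.mark_jitter_px) if spec.mark_jitter_px else 0.0
            # scans keep some margin past the last mark (the bent tube end
            # is cropped away); marks never hug the frame edge
            if x >= w - 20:
                break
            t_k.append(t)
            x_k.append(x)
            t += spec.mark_interval_h
        for x in x_k:
            c = int(round(x))
            c0, c1 = max(c - half_mark, 0), min(c + half_mark, w - 1)
            stroke = interior[:, c0 : c1 + 1]
            canvas[:, c0 : c1 + 1][stroke] = np.maximum(
                canvas[:, c0 : c1 + 1][stroke] - spec.mark_depth, 3.0
            )
        marks_x.append(np.array(x_k))
        marks_t.append(np.array(t_k))
        band_x.append(apexes.copy())
        tube_growth.append(float(v_k))

    # boundary strokes drawn last so tube content never overwrites them
    for y in line_y:
        for x in range(w):
            r0 = int(round(y[x])) - half_thick
            r1 = int(round(y[x])) + half_thick
            canvas[max(r0, 0) : min(r1, h - 1) + 1, x] = spec.boundary_darkness

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    img = RaceTubeImage(
        pixels=pixels,
        source_path="",
        pack_name=f"synthetic-{spec.seed}",
        orientation_applied="none",
    )
    truth = GroundTruth(
        boundaries=boundaries,
        marks_x=marks_x,
        marks_t=marks_t,
        band_x=band_x,
        tube_growth_px_per_h=tube_growth,
        spec=spec,
    )
    return img, truth
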