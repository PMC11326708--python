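# Methods

`racetube` quantifies circadian rhythms of filamentous fungi from scanned
race-tube images. A race tube is a ~40 cm glass tube with an agar layer
along which the fungus grows; under constant darkness, circadian-gated
conidiation leaves periodic dense bands along the tube, so the spatial axis
encodes elapsed time. Daily pen marks at the growth front anchor pixel
position to clock time. This note records the models, parameter choices,
and numerical decisions behind the pipeline.

## Image normalization

Every input is reduced to an 8-bit greyscale grid of exactly 400 × 1160
pixels (the aspect ratio of the straight portion of a standard six-pack).
Colour images are collapsed with the ITU-R BT.601 luminance weights
(0.299, 0.587, 0.114); alpha channels are dropped, since scans carry no
meaningful transparency. Resizing uses bicubic interpolation on a
float-valued image, followed by round-half-to-even quantization and
clipping to [0, 255]; resampling at native size is an exact identity.
Orientation (rotations/flips) is explicit user input, applied before
conversion, never auto-detected. Because all downstream periods are
expressed in hours via the per-tube time-mark calibration, moderate
anisotropic stretching introduced by the fixed-size resize cancels out of
the results; the acceptance suite verifies this by re-analyzing a 15 %
width-cropped, re-stretched copy of a pack.

## Tube-boundary detection

Two redundant detectors run on every image and the larger set of
acceptable lines wins (ties go to the edge-based method):

1. **Canny + probabilistic Hough.** Canny edge detection with hysteresis
   thresholds 1 and 25 on the raw 0–255 gradient scale (Gaussian
   presmoothing, σ = 1), then a progressive probabilistic Hough transform
   (vote threshold 10, gap 3) keeping segments of length ≥ 300 px whose
   extrapolated rise over the full width is ≤ 5 px. Segments are extended
   to full width; candidates closer than 20 px are averaged together. The
   Hough sampling is internally seeded, so detection is deterministic.
2. **Vertical densitometry.** Mean brightness per image row over a 58 px
   strip at the left edge and another at the centre; local minima
   (prominence ≥ 5 brightness units) of the two profiles are paired when
   their rows agree within ~3 px, and the line through the two strip
   centres is extended to full width.

Both candidate lists then pass a *darkness filter*: the mean brightness
sampled along a candidate's path must be below 0.7 × the image median.
Real inter-tube margins are dark; this rejects pseudo-lines that the Hough
transform can assemble from noise edges running across bright tube
content, which would otherwise split a tube in two and shift the tube
numbering. The image's top and bottom edges act as implicit boundaries;
regions shorter than 15 px are discarded as slivers, and at least two tube
regions must remain. Declarative overrides (add/remove a boundary at a
given row) replace the interactive review step of a GUI.

## Densitometry and feature detection

Each tube region is collapsed to a trace of mean brightness per column,
restricted to the rows strictly between its two (possibly sloped) boundary
lines — the raw densitometry. Two Savitzky–Golay variants follow:

* order 4, window 45 px (*band smoothing*): suppresses pixel texture while
  preserving the broad conidial peaks. The window is roughly half a band
  at typical scale (22.5 h × 4.17 px/h ≈ 94 px).
* order 8, window 31 px (*mark smoothing*): the high order tracks the
  sharp, narrow notch left by a felt pen, so its minimum stays on the ink.
  Simulation: a 3 px, 100-unit notch keeps ~57 % of its depth and its
  exact location through this filter (the order-4 filter keeps far less).

**Pen marks** are local minima of the mark-smoothed trace that satisfy all
of: prominence ≥ 15 brightness units; sustained flank slope ≥ 3 units/px
(mean rise from the minimum to the edge of a ±5 px flank window — the
discriminator between ink notches, which rise tens of units over a few
pixels, and band troughs at ~1 unit/px); separation ≥ 20 px (a high-order
filter rings around a deep notch, leaving sidelobe minima ±11 px away that
must not register as marks); and distance ≥ 15 px from either trace end,
where edge polynomial fits are unreliable. Clock times attach to detected
marks either as an explicit list or as `0, Δ, 2Δ, …` hours for a fixed
marking interval Δ (default 24 h). Marks are detected per tube; they need
not align vertically across tubes.

**Mark excision.** The trace inside ±12 px of each mark is replaced by the
straight line joining the values just outside the window (overlapping
windows merge; windows clipped at a trace end hold the surviving anchor).
Values outside the windows are never touched, and flat or linear traces
are exact fixed points. In the pipeline this bridging is applied to the
raw trace *before* band smoothing and once more after: smoothing an
un-bridged trace would smear the ink notch across the 45 px window,
depress the bridge anchors, and fabricate small bumps between marks.

**Band peaks** are local maxima of the smoothed, interpolated trace with
width ≥ 10 px, prominence ≥ 8 units, and separation ≥ 30 px (no two
conidial bands can sit closer than the shortest circadian period, ~58 px
at typical growth rates). All detector thresholds are keyword arguments;
the defaults were tuned on the synthetic suite. Every detector supports
declarative add/remove overrides applied after detection.

## Calibration and growth rate

The pixels-per-hour growth rate of a tube is the mean over consecutive
mark pairs of Δx/Δt (growth is not perfectly linear; the mean of
per-interval rates matches how the marks are laid down). A least-squares
slope through all marks is available behind a flag. If the user supplies
the measured physical distance (mm) between the first and last marks,
mm/px = distance / pixel span converts the rate to mm/h; otherwise the
growth rate is reported as N/A. Pixel rescaling with the same physical
measurement leaves the mm/h rate invariant (the px units cancel).

## Period estimation

All four estimators operate on a user-selected window between two marks
(default: first to last), with hours-per-pixel from the windowed marks.
The search band defaults to 14–40 h: an unrestricted argmax can land on
harmonics or residual trend, while this band brackets the free-running
circadian range (~22.5 h for wild-type-like *Neurospora*) with wide
margins.

* **Linear regression:** period = mean spacing of consecutive band peaks
  (px) × hours-per-px. Needs ≥ 2 peaks in the window.
* **Sokolove–Bushell (χ²) periodogram:** for each integer candidate period
  P px in the band, the series is folded into K = ⌊N/P⌋ complete rows and

      Q_P = K · Σ_h (X̄_h − X̄)²  /  [ (1/(N−1)) · Σ_i (X_i − X̄)² ]

  with column means X̄_h over the K rows and the grand mean/variance over
  all N samples. This is the normalization as printed in circadian
  software; it differs from some textbook forms by constant factors that
  do not move the peak. The peak is the in-band argmax, converted to
  hours. Constant series are rejected. Note the χ² statistic is also large
  at integer multiples of the true period; the band cap at 40 h limits,
  but does not eliminate, harmonic picks for short periods (τ ≤ 20 h
  places 2τ inside the band), which is why the recovery criterion for this
  method is stated as a median.
* **Lomb–Scargle periodogram:** the classical normalized form

      P(f) = ½ [ (Σ X cos ω(t−τ))² / Σ cos² ω(t−τ)
               + (Σ X sin ω(t−τ))² / Σ sin² ω(t−τ) ],   ω = 2πf

  with tan(2ωτ) = Σ sin 2ωt / Σ cos 2ωt, on a mean-centred series over a
  frequency grid of spacing 1/(16 N) covering the band (16× oversampling;
  5× would give ~1.6 px period resolution at the circadian peak, coarser
  than the recovery tolerances below). For a unit sinusoid the power at
  the true frequency approaches N/4, which the tests verify against both a
  literal transcription and scipy's implementation.
* **Continuous wavelet transform:** complex Morlet (centre frequency 1.0,
  bandwidth 2.5 — the sharper scale peak halves the period bias relative
  to bandwidth 1.5) over 100 log-spaced scales spanning the band, computed
  on the linearly detrended trace (the growth-front brightness gradient
  otherwise dominates low frequencies; SB/LS are only mean-centred by
  default). The signal is reflection-padded by one maximum period to damp
  transform edge effects. The per-time ridge is the period of maximal
  amplitude; ridge points are accepted when their amplitude exceeds 75 %
  of the global maximum *and* they lie at least one maximum search period
  away from either window end (a cone-of-influence mask — without it the
  ridge near the ends reflects truncated signal content and biases the
  mean by several tenths of an hour). The tube's period is the mean of
  accepted ridge periods; the slope of the best-fit line through the
  accepted (time, ridge period) points, in hours of period per hour of
  elapsed time, diagnoses period drift (fewer than two accepted points
  reports slope 0 with a warning).

Each method can fail independently (too few peaks, degenerate series,
window too short); `all_periods` returns per-method error markers rather
than aborting the rest.

## Statistics

For any selection of per-tube periods from one method: mean, sample
standard deviation (ddof = 1; a population-SD flag exists for
bit-compatibility checks), and SEM = SD/√n. Selections must be non-empty
and single-method.

## Synthetic packs and what they do (not) show

The generator renders the anatomy of a scanned pack with exact ground
truth: n tubes (default 6) between dark boundary lines (brightness 30,
3 px thick, optional tilt); a background of 180 with a 15-unit
bright-to-dark ramp emulating the growth-front gradient; raised-cosine
conidial bands of amplitude `band_contrast` (default 60) at spatial period
τ·v px; 3 px pen strokes every 24 h of simulated growth (placement jitter
σ = 1 px, stopping 20 px before the frame edge, as scans keep margin past
the last mark); and additive Gaussian pixel noise (default σ = 5, clipped
to [0, 255]). Defaults mirror a canonical wild-type-like experiment:
τ = 22.5 h at v = 4.1667 px/h, i.e. 93.75 px bands and 100 px between
marks. Tubes of one strain share τ but not everything else: each tube
draws its own growth rate (CV 2 %) and band phase (≤ 16 px offset), which
gives the six-tube SEM a realistic magnitude — identical clone tubes would
make it degenerate. Bands span an integer number of full cycles placed
wholly inside the frame, so the analytic apex list is an exact target for
the peak detector. Everything is deterministic for a fixed seed.

Simulated bands are noiseless raised cosines on a clean background; real
scans have mycelial texture, uneven illumination, condensation, and
marker smears. Passing the synthetic suite therefore demonstrates the
correctness of the algorithms and their noise robustness up to σ ≈ 10,
not performance on degraded scans — that is what the detector overrides
are for.

## Verification conditions

The end-to-end tests run at these problem sizes, chosen to exercise the
estimators well past their asymptotic behaviour while keeping the default
suite fast: 50 seeded packs with τ ~ U(18, 26) h at noise σ = 8 for period
recovery (median |τ̂ − τ| ≤ 0.3 h for LR and LS, ≤ 0.5 h for SB and CWT;
a noiseless canonical pack must land in [22.0, 23.0] h for all four
methods); 100 seeded packs with 3–8 tubes, contrast U(40, 80), noise
U(0, 10) and tilt ∈ {0, 1, 2} px for feature detection (≥ 95 % of interior
boundaries within 3 px, every mark within 2 px, band counts exact);
oracle equivalence of both periodograms to literal loop transcriptions at
relative 1e−9 on 50 random series. One further check — a benchmark on
real scans of a classical banding strain (mean LR/SB periods expected in
22.2–22.7 h) — runs only when such scans are placed under
`tests/data/benchmark_scans/`, since those images cannot be bundled here.

## Known limitations

* Mark positions shift by up to ~13 px when a pen mark lands on a band
  apex: the bridge chord replaces the apex and the detected peak moves to
  a chord endpoint. Band *counts* survive this; linear-regression periods
  absorb it as ~0.1 h noise.
* The SB statistic's harmonic ambiguity for τ ≤ 20 h (see above).
* No correction for non-linear growth within a mark interval; the
  calibration is piecewise linear by construction.
* Curved tubes and the bent tube ends are out of scope; images are assumed
  cropped to the straight portion.
* Periodogram peaks carry no significance testing; the tool reports the
  in-band maximum regardless of rhythm strength.
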