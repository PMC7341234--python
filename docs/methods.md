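# Methods

## The activity index

The activity index (AI) measures flock movement intensity from top-view
video without tracking individuals. For each pair of frames separated by a
sampling interval Δ, pixels whose intensity changed by more than a
threshold τ form a binary motion mask; the mask's pixel count is divided by
`S(t−Δ)`, the number of bird-representative pixels in the earlier frame.
Normalising by bird pixels rather than frame area compensates for bird size
and number, so values at different ages are comparable. AI carries no
direction information (it is not optical flow) and measures horizontal
motion only; vertical movements such as standing up or pecking are outside
its reach.

Per-pair AIs are summed over fixed 300-s **cumulative windows**; the window
is the unit of statistical analysis. Each interval's cumulative AI is also
expressed as a percentage of the full-frame (0.04 s at 25 fps) baseline
within the same window, which is how the accuracy cost of coarser sampling
is quantified.

### Threshold calibration

τ = `fraction` × (maximum pixel intensity over the first
`calibration_frames` frames of the clip), defaults 0.15 and 20. The leading
frames are assumed to show empty background; calibrating on them makes τ a
per-clip noise floor covering sensor noise and lighting variation. The
phrase "maximal intensity of the clip" is ambiguous between the
calibration run and the whole clip; the calibration-run maximum is the
default and `use_full_clip=True` selects the alternative. Note that with
birds present in later frames the whole-clip maximum includes bird plumage
and is typically higher.

### Mask modes

The difference rule as usually printed, `I(t) − I(t−Δ) > τ`, is one-sided:
a bright bird leaving a dark patch fires the mask only at its new location.
`mode="onesided"` reproduces that rule literally; the default
`mode="absolute"` uses `|I(t) − I(t−Δ)| > τ`, standard motion-detection
practice that also counts darkening pixels. Both use a strict inequality.
Differences are computed after widening to signed integers; subtracting
uint8 frames directly would wrap around and silently corrupt the mask.

### Bird-pixel segmentation

No standard procedure exists for estimating `S(t)` in this setting, so the
package uses the simplest estimator that relies only on in-clip
information: the reference background is the per-pixel median of the
calibration frames, a pixel is bird if it deviates from the reference by
more than a threshold (default: the same τ), and 4-connected components
smaller than `min_blob_area` (default 4 px) are discarded as speckle. When
`S(t−Δ) = 0` the AI of that pair is recorded as missing (NaN), never a
division by zero; aggregation skips missing values and reports their count.

### Windows and ratios

Samples are assigned to windows by current-frame timestamp, half-open on
the left: window k covers `(k·300, (k+1)·300]` seconds. This makes every
300-s window hold exactly `300/Δ` pairs at every admissible interval —
7500 at 0.04 s down to a single pair at 300 s — and in particular gives
the 300-s interval's one pair per window a home in the window whose motion
it summarises. Only complete windows are emitted; a trailing partial
window is dropped (a 56-min clip therefore yields 11 windows). Ratios are
computed per window and then averaged (mean of ratios), because the
per-window ratio is the quantity with a meaningful standard error; the
pooled ratio of means is reported alongside as `ratio_of_means_pct`.
Windows with zero baseline AI are excluded from ratios and logged. SEM is
the plain `sd/√n` of the windows in a group; it is reported as missing for
singleton groups.

## The synthetic flock generator

No field video ships with the package; the simulator generates sequences
with the statistical structure the analysis assumes, plus exact ground
truth, so every stage is testable offline.

**Scene.** A square arena of `arena_px` = 200 px at 0.00355 m/px and
25 fps — the study's region-of-interest geometry. The litter background is
a static per-pixel texture, uniform on `background_intensity ±
background_texture` (65 ± 20), with additive Gaussian sensor noise of
`noise_sd` = 2 intensity units per frame. Birds are filled, hard-edged
(non-anti-aliased) ellipses of semi-axes (14, 9) px at intensity 200, so
the bird mask, bird-pixel count and pair-wise changed-pixel count have
exact integer ground truth. The first 20 frames are bird-free, mirroring
the empty-background calibration the analysis performs.

**Motion.** Each of `n_birds` = 5 birds alternates exponential
moving/resting bouts (mean rest bout 4 s; moving-bout mean set so the
long-run resting fraction equals `resting_prob` = 0.5). During a moving
bout the bird walks at a lognormally perturbed speed around `speed_mean` =
0.08 m/s along a smooth curved path: heading advances by a per-bout
constant turning rate (drawn from N(0, 0.6 rad/s)) plus a small per-frame
perturbation (sd 0.01 rad), with reflecting walls. The smooth-turning
choice matters: if heading were re-drawn each frame the body orientation
would jitter at 25 Hz, rotation would accumulate as √t rather than t, and
the 0.2-s interval would spuriously lose ~30% of the measured activity.
Real walking is smooth at sub-second timescales, which is what "continuous
motion" means here.

**Transients.** Independently of locomotion, each bird starts a transient
event at `transient_rate` = 4 per bird-minute: for `transient_duration` =
0.3 s its rendered outline jitters around the base pose (per-frame offsets,
sd 1.5 px) and then returns exactly to base. These emulate sub-second
turning/bobbling/preening/shaking. Because the bird ends where it started,
frames further apart than the event see nothing — the mechanism by which
long sampling intervals underestimate activity, demonstrated quantitatively
in the test suite.

**Noise discipline.** The generator enforces `3·noise_sd < τ` (approximated
at validation time as 15% of the brightest background pixel), so noise
alone cannot fire the motion mask. With the defaults, τ calibrates to ≈13
and the false-positive probability per pixel pair is ~10⁻⁶.

**Age presets.** `config_for_week` maps weeks 1–7 onto a single activity
scalar (1.6 down to 0.45) scaled into speed, resting fraction and body
size. It exists so age-by-location style summaries can be exercised
end-to-end; it makes no claim of biological calibration.

**What the simulator does not emulate:** occlusion boundaries at feeders
and drinkers, lens distortion (an optional user-supplied remap hook exists
in the loader, but no lens model ships), lighting drift within a clip,
bird-bird interaction forces, plumage texture, and anti-aliased edges.
Passing tests therefore validate the *pipeline arithmetic* and the
interval-accuracy mechanism, not detection performance on commercial-house
footage.

## Numerical choices

- Grayscale conversion: BT.601 luma, rounded half-up to the input integer
  dtype — deterministic and testable against hand-computed values.
- Coordinates 0-based, row-major; ROIs half-open `[x0, x0+width)`.
- Timestamps always `index / frame_rate` from filename order; file
  metadata is ignored for reproducibility.
- Subsampling requires `interval × fps` to be an integer stride and keeps
  original timestamps; the returned sequence's `frame_rate` is divided by
  the stride so intervals stay wall-clock and subsampling composes.
- Frames are rendered in float32 and rounded once to the integer bit
  depth; all simulator randomness flows from a single PCG64 generator, so
  equal seeds give bit-identical frames across platforms.
- Window assignment uses a 1 ns slack (`1e-9`) when flooring/ceiling
  timestamps against window boundaries to absorb float accumulation.

## Problem sizes

The interval-sweep experiment used by the tests and the acceptance script
runs 20 independent replicates of one 300-s window each (7 521 frames of
200 × 200 px per replicate) with locomotion only (`transient_rate=0`,
the continuous-motion condition under which near-lossless 0.2-s sampling
is the expected behaviour). One replicate costs ~15 s on one CPU; the
sweep a few minutes. Unit tests use 2–60-s clips and 8 × 8 random frames
for the bit-exact oracle comparisons.

## Known limitations

- The onesided mode systematically undercounts motion of bright birds on
  dark litter (departures are invisible); it is provided for fidelity to
  the printed rule, not recommended for use.
- Segmentation quality on real footage depends on a genuinely empty,
  photometrically stable calibration run; shadows and litter disturbance
  (dust-bathing craters) will be counted as bird pixels.
- Cumulative AI values depend on bird count, size and contrast; absolute
  magnitudes are not comparable across scenes, which is why analysis
  reports ratios to the full-frame baseline within the same clip.
- The simulator's per-window pair-count bookkeeping assumes the clip is an
  exact multiple of the window plus one frame; arbitrary-length real clips
  simply lose the trailing partial window.
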