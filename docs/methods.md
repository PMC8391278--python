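# Methods

## Signal model

A zebrafish embryo at ~24 hpf coils inside its chorion, a spherical shell
that images as a circle. A coil moves the embryo's body over a fraction of
the chorion footprint within a few frames, so in a stack of consecutive
absolute frame differences a coil appears as a brief burst of non-zero
pixels confined to one chorion. Averaging the difference over the chorion's
circular footprint gives one activity trace per embryo:

    trace[t] = mean over pixels inside the circle of |frame[t] − frame[t−1]|

with trace[0] defined as 0 (the difference stack keeps the source frame
count by zero-padding its first frame, so trace index equals frame index).
All intensities live on an 8-bit [0, 255] scale — deeper sources are
rescaled on read — because every threshold in the method (start threshold
3, minimal amplitudes around 0.6–0.95) is quoted on that display scale.

Two independent readouts are taken from each trace and combined per embryo:

* **Peaks** (coil counts and intensities): maxima under a minimal-amplitude
  and minimal-peak-distance constraint.
* **Events** (coil durations and intervals): threshold-crossing episodes
  opened by a frame-to-frame rise and closed at an end level.

The summary mixes them deliberately — frequency and mean intensity are
peak-derived, mean duration and mean interval are event-derived — mirroring
the two parallel extraction paths of the workbook layout (sheets TC,
Intensity, Interval, Duration, Summary).

## ROI detection

Chorions are found on a single reference frame (frame 0 by default; slow
embryo drift during a one-minute recording is tolerated, not tracked):

1. Gaussian blur (`blur_sigma`, default 4 px at 720p — scale with image
   size; the synthetic 240×320 dishes use 2 px) thickens the chorion
   annulus.
2. IsoData (iterative intermeans) binarization: starting from the
   mid-range, iterate t ← round((mean ≤ t + mean > t)/2) to a fixed point.
   IsoData adapts to global intensity offsets, which Otsu-style criteria
   handle less gracefully on low-contrast backgrounds. Foreground is the
   *minority* class of the binarized frame, so bright-on-dark (darkfield)
   and dark-on-bright (brightfield) dishes both feed the same Hough stage.
3. Circle Hough voting: for every candidate (cx, cy, r) on the search grid,
   the score is the fraction of the midpoint-rasterized perimeter supported
   by foreground within a 1-pixel tolerance band (foreground dilated by a
   3×3 element). Candidates with score ≥ `score_threshold` (default 0.7)
   are accepted greedily in descending score order subject to centers at
   least `min_center_spacing` apart (default `r_min`; chorions cannot
   interpenetrate, and this suppression also removes the tangent-type false
   circles that can osculate a real ring from inside).

Because a blurred annulus is several pixels thick, a whole plateau of
candidates can reach a perfect score; reporting the lexicographically first
plateau member would bias centers toward the plateau corner by ~3 px. An
accepted detection is therefore reported as the centroid of its equal-score
plateau (all same-score candidates within the suppression radius), which
brings center error on synthetic dishes to ~0.2 px. The candidate-set
semantics make threshold behaviour provable: the candidate list at a higher
threshold is a prefix of the list at a lower one, so detection sets are
nested (0.9 ⊆ 0.7 ⊆ 0.5) and detection count is monotone in the threshold.
The egg count is never an input; the data decides.

Score counts are computed as exact integers (shift-and-add voting), so the
implementation agrees bit-for-bit with a brute-force accumulator, which the
test suite checks on 64×64 masks.

## Enhancement

Before differencing, each frame passes (in order) Gaussian blur → unsharp
mask → highpass:

* blur: σ = 1 px default; suppresses sensor noise.
* unsharp: `(image − w·blur_r(image)) / (1 − w)`, radius 2 px, weight 0.6;
  restores edge contrast.
* highpass: `image − blur_r(image) + 128`, radius 10 px; removes
  illumination structure slower than ~40 px while preserving mid-grey.

All convolutions use reflect padding (no dark borders contaminating edge
ROIs). The enhanced frames are quantized back to integer grey levels —
8-bit pipeline semantics, the way an 8-bit image analysis program stores
each filter result. Quantization matters more than it looks: it zeroes the
sub-grey residue that a moving neighbor leaks into a resting embryo's ROI
through the highpass background estimate, so a resting embryo's trace is
exactly zero rather than faintly positive. The highpass radius default
of 10 px was set so that ROIs a typical egg spacing apart (≥ ~80 px) sit
beyond 4σ of the background blur and that leakage falls below the
quantization step; a much larger radius (e.g. 25 px) reaches ~3σ into
neighbor ROIs and audibly smears motion across embryos.

## Peak extraction

The amplitude filter is the classic alternating-extrema scan: walking the
trace, the running maximum is confirmed once the signal drops by at least
`min_amplitude` below it, then a running minimum accumulates until the
signal rises by `min_amplitude` above it, and so on. Amplitude is therefore
prominence-style — a rise relative to the retained minima flanking the
peak — so baseline drift cannot promote noise into coils. Plateau maxima
resolve to their first frame. `min_amplitude = 0` degenerates to plain
strict local maxima.

The distance filter then suppresses confirmed maxima greedily: tallest
first (ties kept at the earlier frame), discarding any maximum closer than
`min_distance` frames to an already-kept one. Minima are recomputed as the
lowest point between consecutive surviving maxima, so maxima and minima
alternate. Defaults: `min_amplitude` 0.7 (midpoint of the 0.6–0.8 range
used in validation recordings), `min_distance` 30 frames — the rest time
below which two maxima are one coil. The distance is specified in frames;
convert through the stack's actual fps when thinking in seconds, since
recordings occur at both 30 and 60 fps.

Monotonicity of the peak count in both parameters is not proved for the
greedy suppression, but held without exception over 3×10⁵ randomized
trace/parameter probes during development; the suite asserts it on seeded
random and synthetic traces.

## Event segmentation

With the trace scanned in frame order while outside an event, an event
opens at frame t when `trace[t] − trace[t−1] ≥ start_threshold` (default 3
grey levels; a single-frame rise, which is what makes a too-high threshold
miss slow-rising coils). It closes at the first subsequent frame at or
below the end level, that frame included in the duration; an event still
open at the last frame closes there. The end level is either a literal
value or (default) the median of the whole recording, zeros included — a
self-calibrating estimate of each trace's noise floor.

The median default has a sharp statistical consequence worth knowing: on a
continuous noise floor roughly half of the quiet frames lie above the
median, so the closing frame lags the true burst end by a geometric number
of frames (P(lag ≥ k) ≈ 2⁻ᵏ). On noise-free traces the floor is exactly
zero and closure is exact; on noisy recordings, if frame-accurate durations
matter, set the end threshold explicitly above the noise floor — e.g. at
pixel noise σ ≈ 1 the enhanced trace floor is ≈ 0.05 grey, and an end level
of 1.0 closes events within a frame. This is the same rethresholding loop
the workflow already provides for its four classic failure modes (runaway
duration ← end level too low; premature stop ← end level too high; missed
start ← start threshold too high; many short false durations ← start
threshold too low); an optional minimum-duration filter (default off)
guards the last one. `reprocess` reruns segmentation with new thresholds
and replaces, never merges, prior results.

Intervals are the gaps between consecutive events, in seconds. Recordings
with 0 or 1 events have no defined interval and report empty cells, never
zeros. Per-embryo endpoints: `tc_frequency` = maxima count / recording
minutes; `mean_intensity` = mean maxima height (the maxima height on the
difference trace, not the prominence, is what "coil intensity" means here);
`mean_duration_s`, `mean_interval_s` = means of the event-derived lists.

## Synthetic data

The generator renders what the pipeline assumes and nothing more: a dish of
non-overlapping chorions (bright annuli, radius 18–24 px by default, grid
or random layout) each holding an elongated blob (ellipse with semi-axes
0.6r × 0.25r) that rotates inside its chorion during scheduled bursts.
Rotation runs at constant angular speed (total angle π per burst at the
default amplitude), so a coil's difference-trace signature is a roughly
rectangular pulse with a one-frame onset — the sharp rise a real coil
produces and the start-threshold rule requires. Contrast is set so pulses
peak near 7 grey levels through the default enhancement chain, the scale of
reported coil intensities in untreated embryos. Darkfield is rendered
directly; brightfield is its 255-complement. Additive Gaussian pixel noise
and a fixed seed (bit-reproducible) complete the model.

Study conditions used by the recovery tests: 12 eggs on a 240×320 frame,
60 s at 30 fps (1800 frames), 2–8 coils per embryo of 20 frames each,
bursts ≥ 70 frames apart; the trace-length check uses 60 s at 60 fps (3600
frames). These sizes keep the full suite within desk-scale runtimes while
preserving the recording geometry that matters (egg spacing ≈ 4 radii,
coil rest times ≥ 2× the peak-distance threshold).

What the generator does **not** model — chorion translucency, embryo drift
between coils, illumination flicker, camera compression artifacts —
bounds what the recovery results mean: they certify the pipeline's
arithmetic and its thresholds on clean recordings, not its robustness to
pathological optics. Trace-level simulation (`simulate_trace`) bypasses
optics entirely: raised-cosine bumps (the morphology of real activity
plots) or rectangular pulses for oracle tests, plus clipped Gaussian noise.

## Numerical and interface choices

* Strict-interior circle membership (pixel center inside the circle) makes
  every ROI mean reproducible by a naive pixel loop; border ROIs average
  over their in-frame pixels only.
* Absolute (unsigned) frame difference: a coil must register whichever way
  the local intensity moves.
* IsoData iterates on rounded intensities with histogram cumulative sums;
  a uniform image returns its single value, an empty foreground, and a
  warning. The fixed point is verified against an exhaustive 256-candidate
  scan in the tests.
* Frame indexing is 0-based; time in seconds is frame/fps; frame order for
  image-sequence input is lexicographic.
* AVI/MP4 containers are read through imageio when a video backend is
  present; multi-page TIFF and PNG sequences are first-class and carry no
  frame rate, so `fps_override` is mandatory for them.
* The workbook mirrors every sheet as CSV so results remain inspectable
  and diffable without a spreadsheet reader; sheet and column order are
  bit-stable across runs.
* The pipeline is deterministic given input and configuration; the run
  manifest (parameters, input checksum, outputs) reproduces a run exactly.

## Known limitations

* One reference frame per recording: embryos that drift far from their
  chorion's detected footprint dilute their own trace.
* The Hough score rewards perimeter coverage only; overlapping chorions or
  strongly elliptical eggs need a relaxed score threshold and tighter
  radius bounds.
* Coiling sub-structure (double flexions within one rest time) merges into
  a single counted coil by construction of the distance filter.
* The median end level biases durations upward by ~1 frame on noisy
  recordings (see above); frame-accurate duration studies should set a
  literal end level.
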