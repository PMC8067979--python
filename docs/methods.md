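# Methods

## Signal model and conventions

Recordings are fixed-rate 100 Hz tables of six channels, accelerometer in
m/s² and gyroscope in °/s, with z vertical, y mediolateral, x
anterior-posterior for a lower-back (L5) placement. Frames are indexed from 0
and all intervals are half-open `[start, end)`, which keeps set arithmetic
(gap detection, boundary exclusion) unambiguous. Loading rejects NaNs and
non-numeric cells instead of repairing them: implausible stretches of
free-living data are better excluded than interpolated. The standing-offset
correction uses 9.81 m/s² as the nominal vertical reading and applies only to
the accelerometer; gyroscope bias is not modelled. Which standing frames to
pool (per session, per subject) is left to the caller, who passes explicit
intervals.

## DTW core

`dtw_align` uses the classic three-step pattern (i+1,j), (i,j+1), (i+1,j+1)
with local cost |q_i − t_j| and no slope or band constraint, applied per axis
(samples are scalar, so the Euclidean local distance reduces to the absolute
difference). The accumulated distance is deliberately **not**
length-normalised: the maximum-acceptable-distance thresholds are expressed
on the raw accumulated scale, and normalising would change their meaning.
Equal-cost predecessors are resolved diagonal-first, then query-advance, then
template-advance — this makes paths deterministic and as short as possible.
The DP kernels are numba-compiled; a two-row distance-only kernel serves bulk
computations (medoid search, threshold calibration) where no path is needed.

Stretch regions are maximal path runs in which one **template** frame absorbs
consecutive query frames; run length is counted in query frames and compared
against a fraction (default 10 %) of the template length. Only this
orientation is used: the window is 1.5 templates long by construction, so
surplus query frames pile up against border template frames.

`refine_and_score` proposes candidate sub-windows from every pair of
stretch-region borders, plus the two template-length sections flush with the
window borders. The latter matter for quasi-periodic signals: warping away an
extra stride can spread its cost so evenly along the path that no single
stretch run reaches the detection size, yet the surplus still sits at a
border. Candidates shorter than 40 % of the template are discarded (shorter
events are implausible at stride scale), the untrimmed window always remains
in the pool, and ties are broken by earliest start then shortest section —
consequently the refined distance never exceeds the untrimmed one.

## Template construction

DBA is initialised with the medoid snippet (smallest summed DTW distance to
the rest, first index on ties) resampled to the target length by linear
interpolation; snippets themselves are never resampled — DTW handles length
differences. Each iteration replaces every average sample by the mean of the
snippet samples aligned to it. With an L1 local cost the mean update is not
guaranteed to reduce the objective at every step, so the loop keeps the best
average seen and stops as soon as the mean DTW distance fails to improve by
`tol` (default 1e-6); the reported objective history is therefore
non-increasing. The reference length per activity is the median snippet
length rounded to the nearest integer, robust to occasional truncated or
outlier strides.

## Recognition

Sliding-window matching uses a window of `round(1.5 × L)` frames (L =
reference length) and advances to `section_end − round(0.25 × L)`; the 25 %
overlap is measured against the reference length, not the matched section, so
the step size is deterministic. Gap handling: gaps shorter than 25 % of L
inherit the ED and section length of the better-scoring neighbour; gaps of
25–75 % get one refinement pass; longer gaps re-enter the sliding loop (the
two published gap rules do not cover them, and re-entering guarantees full
coverage). The loop is bounded with a nearest-neighbour fill as a terminal
safety net, so every frame is assigned exactly once.

The probability formula `P = 101 − 101^(ED/threshold)` is the unique simple
form meeting both anchor conditions (P = 100 at ED = 0; P = 0 at ED =
threshold); the comparison is implemented as P = 0 for ED ≥ threshold, which
coincides with the formula at equality. Axis combination is a weighted
arithmetic mean — it preserves the [0, 100] scale and the two special rules:
the vertical-axis double weight (applied to walking only, where that axis
alone is highly discriminative; configurable) and the veto that forces the
combined probability to 0 when ≥ 3 used axes read 0. The length penalty
interprets "activity length" as the matched section's length in frames; since
sections are found per axis but the penalty is defined per activity, the
median section length over the activity's used axes is used. Classification
ties are broken in the fixed order walking → ascending → descending; exact
ties are measure-zero on real signals but must be deterministic.

All tunables (window factor 1.5, stretch fraction 0.10, minimum window 0.40,
overlap 0.25, gap bounds 0.25/0.75, zero-axes cutoff 3, length cutoff 0.5,
thresholds, axis sets and weights) live in `RecognitionConfig` with these
defaults and serialise to YAML/JSON. The default threshold table is valid
only for 100 Hz signals in physical units with the canonical orientation; for
any other source — including the synthetic generator — thresholds should be
re-derived with `calibrate_thresholds`, the 95th percentile of within-class
snippet-to-template distances per (activity, axis).

## Evaluation

Frame-level, one-vs-rest. Only frames covered by a gold interval participate;
gold labels outside the three locomotion classes act purely as negatives
("others" row), and configurable labels (default `undefined`, `walking with
transition`) are dropped entirely. `exclude_boundary_frames` shrinks each
locomotion interval by 100 frames (1 s) per side and drops intervals that
vanish; the removed frames leave the evaluation rather than becoming
negatives, since predictions there are neither right nor wrong once the
period's edges are declared unrepresentative. Sensitivity is TP/(TP+FN),
specificity TN/(TN+FP), both in percent; degenerate cases (no positives, no
negatives, no evaluable frames) yield NaN and an explicit empty flag instead
of a silent 0.

## Synthetic data generator

The generator emulates the structure of free-living lower-back recordings,
not their biomechanics: locomotion segments are concatenations of stride
waveforms, each axis a 1–3-component harmonic mix over the stride phase,
with per-stride duration drawn from a normal distribution and a per-stride
amplitude jitter; white noise is added per channel family; standing and
sitting are low-variance noise around an upright or ~20°-tilted gravity
vector. Defaults: walking strides 1.00 ± 0.05 s, ascending 1.40 ± 0.07 s,
descending 1.15 ± 0.06 s; vertical-axis amplitudes ~2–3.5 m/s² dominated by
the step (2-per-stride) harmonic, gyroscope amplitudes 10–30 °/s; 10 %
amplitude jitter; accelerometer noise 0.3 m/s², gyroscope noise 3 °/s —
values a movement scientist would call plausible for older-adult gait at L5.
Class separation lives in stride duration, amplitude ratios and harmonic
content and is deliberately partial, so cross-class confusion remains
possible. The first and last full stride of every locomotion segment is
attenuated (×0.7 amplitude, ×0.85 duration), reproducing the attenuated
initiation/termination strides seen in real gait — which is why excluding
the first/last second of each period raises measured sensitivity. The default
schedule is a ~10-minute mix of walking, both stair directions, standing and
sitting. `apply_tilt` rotates both 3-vectors rigidly (intrinsic x-y-z Euler
angles) to emulate sensor misplacement.

What passing on synthetic data does **not** show: robustness to real
biomechanical variability (asymmetry, shuffling, turning), soft-tissue
artefacts, sensor drift, or the published threshold table's validity — the
synthetic workflow calibrates its own thresholds. It does exercise every
algorithmic branch (stretch trimming, gap rules, vetoes, penalties,
boundary exclusion) against exact ground truth.

## Problem sizes and determinism

The standard experiment builds templates from one ~10-minute recording
(≈ 400 strides; DBA over up to ~270 snippets per axis) and recognises a
second recording of the same schedule generated with a different seed —
about 61 000 frames × 14 (activity, axis) streams — in well under a minute in
total. Everything is deterministic given the simulation seeds: DTW
tie-breaks, medoid initialisation and the generator's single `numpy`
Generator per run.

## Known limitations

Three locomotion classes only; no streaming mode; no magnetometer; input must
be 100 Hz. Descending stairs is the weakest class here as in real data —
its harmonic signature overlaps walking's, and short 40–45 s segments give
DBA fewer strides to average. The default thresholds are configuration, not
constants: any change in units, rate or population invalidates them, which is
the reason `calibrate_thresholds` exists.
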