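# Methods

Models, parameter choices and known limitations of each stage. All
defaults named here are the values in `StageParams` and `SceneConfig`;
every one is recorded in the run manifest.

## Synthetic movie model

The generator is the package's source of ground truth, so its model is
spelled out completely.

**Geometry.** Default scenes are 128×128 px, 350 frames at 2 s/frame,
with the stimulus window opening at frame 40 for 100 frames, and 10–15
Z planes (`n_z=12` by default; the benchmark suites use `n_z=5` to fit
single-CPU time budgets — Z only enters through the maximum projection,
and the defocus weighting makes extra planes nearly redundant).

**Neurons.** Each soma is an isotropic Gaussian intensity blob with
`sigma = radius/2` (default radius 4 px). Its ground-truth mask at each
frame is the set of pixels above 10 % of the blob's peak. The standard
paired scene places a bright neuron (baseline 400 counts, fast kinetics)
left of a dim one (180 counts, slow kinetics), reflecting the large
brightness asymmetry typical of such pairs.

**Response kernel.** The stimulus multiplies a neuron's brightness by
`1 + A·k(t)` where `k(t) = c·(1 − e^(−t/τr))·e^(−t/τd)` is normalized to
unit peak; its analytic maximum is at `t* = τr·ln(1 + τd/τr)`. Kinetic
presets: fast (τr 2.5 s, τd 6 s) and slow (4 s, 15 s). Response classes
map to amplitudes A: absent 0, moderate 0.5, high 1.6.

**Motion.** Whole-field integer drift is a rounded Gaussian random walk
(step SD 0.3 px/frame) plus occasional twitches (probability 0.02/frame,
up to 4 px). The shift applies to the entire field, matching a
semi-restrained animal sliding in a trap; per-neuron independent motion is
not modeled.

**Optics and noise.** Each Z plane sees the scene scaled by a defocus
weight (triangular profile peaking at the neuron's focus plane), a linear
background gradient defeats global thresholds, an exponential bleaching
term decays all signal, and the detector applies Poisson shot noise then
Gaussian read noise (SD 3) before casting to uint16.

**Emitted ground truth:** per-frame shifts, per-neuron boolean masks,
noiseless in-mask mean traces, true classes, background series, and the
noiseless projection.

## Registration

Gated exhaustive search over integer shifts `|dy|,|dx| ≤ max_shift`
(default 20). Each candidate is scored by zero-mean normalized
cross-correlation computed over the *exact overlap region* for that
shift — means and variances are recomputed per shift from FFT running
sums (five spectra per frame; the reference-side spectra are precomputed
once per movie), so the surface is identical (to 1e-9) to a direct sliced
computation, which the tests verify. Ties are broken deterministically:
scores are rounded at 1e-9 and the smallest `|dy|+|dx|` (then `dy`, then
`dx`) wins. Frames whose best score falls below `score_floor` (0.3) or
with constant images are flagged. Registered frames are translated with
zero fill; the padding region is excluded from background estimation via
a validity mask.

Limitation: integer translation only, and re-registering an already
registered movie can report ±1 px residuals near zero-padded borders.

## Segmentation

A depth-8 decision tree (min 20 samples/leaf) classifies each pixel from
a feature bank: identity, Gaussian blur (σ 1, 2), median filter (3, 5)
and local range (3, 5) — smoothed channels give robustness to shot noise,
the range channel separates textured somata from smooth background.
Training labels come from ~10 frames; in the synthetic setting the
simulator's masks stand in for manual scribbles (dense 0/1 labels on
frames evenly spaced through the movie, so both baseline and transient
appearance are seen). The label convention is 0 background / 1 neuron /
255 unlabeled. Components under 5 px are dropped and the 2 largest
survivors kept per frame.

A global-Otsu baseline is included; on gradient backgrounds it collapses
(held-out F1 ~0.01 vs ~0.97 for the tree), which is the quantitative
motivation for trainable segmentation.

Limitation — *mask dilation under transients*: when a neuron brightens,
more of its Gaussian skirt crosses the classifier's decision boundary, so
learned masks grow and the in-mask mean under-reports the true peak by up
to ~35 %. Extraction over ground-truth masks recovers simulated
amplitudes within a few percent (the trace-recovery acceptance criterion
isolates exactly this), so the attenuation is attributable to mask
growth, not to the trace arithmetic. The classification thresholds below
therefore operate on the measured scale.

## Tracking

Track heads are linked to per-frame detections by optimal one-to-one
assignment (SciPy `linear_sum_assignment`) on Euclidean centroid
distance, with pairs beyond a 15 px gate forbidden; among assignments
matching the most pairs, total distance is minimized. Unit and acceptance
tests verify equality with a brute-force enumeration oracle. Unmatched
heads coast on their last position; a gap run over `max_gap` (10) frames
terminates the track, which flags the whole movie as unquantifiable (the
automated stand-in for discarding recordings with uncontrolled
movements). New tracks may only open during the first `init_window` (10)
frames. For two-neuron recordings the retained pair is named left/right
by median image column (image frame, not anatomy — orientation in the
trap is arbitrary).

## Traces and classification

Per frame, a neuron's raw value is the mean intensity over its assigned
component; background is the median outside all components dilated by
3 px, excluding registration padding, computed once per movie. Gaps of
≤10 frames are linearly interpolated; border gaps stay missing.
ΔF/F0 uses `F = raw − background`, `F0 = mean of F` over pre-onset
non-gap frames (≥5 required, F0 > 0 required).

Pooling aligns traces at stimulus onset and reports per-offset mean,
sample SD (ddof 1) and n, dropping offsets with fewer than 2
contributors.

Classification takes the peak ΔF/F0 in `[onset, onset + duration +
lag_allow]` (lag 15 frames, allowing slow-kinetics peaks shortly after
stimulus offset): *absent* if the peak clears neither `theta_abs` (0.2)
nor `k_sigma` (3) × baseline noise; *high* at or above `theta_high`
(0.8); *moderate* between. On the 60-movie benchmark suite this triage
agrees with ground truth for ~99 % of neurons; the occasional miss is a
high response measured just under 0.8 after mask-dilation attenuation.

## Static images and compartments

Static quantification measures background-subtracted mean intensity in a
polygon ROI (rasterized by pixel-center containment) or threshold ROI;
background is a drawn polygon's mean or, by default, the median outside
the 3 px-dilated ROI. Compartment mode measures three fixed polygons
(anterior neurite, posterior neurite, soma) on single-plane 10 Hz light
streams of immobilized animals — no registration or tracking — and
normalizes at light onset.

## Statistics

Two-group: both samples pass the normality gate (Shapiro–Wilk p > 0.05
AND Anderson–Darling statistic ≤ 5 % critical value; automatic pass at
n > 30, sub-statistics still recorded) → Student t, switched to Welch
when a two-sided F-ratio test rejects variance homogeneity; otherwise
two-sided Mann–Whitney. Multi-group: all-normal → one-way ANOVA with
Bonferroni-corrected pairwise t tests; otherwise Kruskal–Wallis followed
by Dunn's z comparisons on pooled ranks with tie correction
(`Σ(t³−t)/(12(N−1))` subtracted from the rank variance) and Bonferroni
adjustment. Stars: * ≤0.05, ** ≤0.01, *** ≤0.001, **** ≤0.0001. Every
result carries its decision path (gate outcomes, F-ratio, raw p).

Under a Gaussian null (n = 20 per group, 1000 replicates) the full tree's
empirical type-I rate sits near the nominal 5 % (acceptance bound
[0.03, 0.07]).

## Problem sizes and budgets

Chosen so the full test suite runs on one CPU in well under 25 minutes:
benchmark movies are 128×128 × 350 frames × 5 Z planes (~3 s to simulate,
~5 s to process each); the 60-movie classification suite completes in
~8 minutes; unit tests use 64×64 × 80-frame scenes. The acceptance script
regenerates everything from one seed in roughly the same total time.
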