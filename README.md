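# wormtrace

Calcium-imaging analysis for paired-neuron recordings in *C. elegans*, with
a fully ground-truthed synthetic benchmark.

## What this is for

A common experiment in worm neurobiology delivers a chemical stimulus (for
example hydrogen peroxide perfused into a microfluidic trap) or a light
step to a semi-restrained animal expressing GCaMP in one or two identified
neurons, and records a Z-stack movie of the head. The biological readout
is each neuron's fluorescence transient: is there a response, how big is
it, and how does its magnitude compare across genotypes and stimulus
doses? Getting from raw multi-page TIFFs to that readout takes a chain of
image-processing steps, each of which can silently corrupt the result —
the animal twitches, the two somata differ several-fold in brightness, the
background is uneven, and responses must be normalized before animals can
be averaged.

`wormtrace` implements that chain as a small, testable library:

1. **Projection** — maximum-intensity projection over Z.
2. **Registration** — per-frame integer translation against a reference
   frame by gated, exact-overlap zero-mean normalized cross-correlation
   (every candidate shift inside the gate is scored; no gradient descent,
   no local optima).
3. **Segmentation** — a trainable per-pixel decision tree over a small
   filter bank (identity, Gaussian, median, local range), learned from a
   handful of labeled frames; a global-Otsu baseline is included for
   comparison and is consistently worse on gradient backgrounds.
4. **Tracking** — per-frame components are linked by optimal one-to-one
   assignment (total centroid distance minimized inside a gate), with
   coasting over short detection gaps and automatic flagging of movies
   whose tracks cannot be maintained.
5. **Traces** — per-neuron mean fluorescence, background-subtracted and
   normalized as ΔF/F0 against the pre-stimulus baseline; traces are
   pooled across animals after aligning to stimulus onset.
6. **Classification** — each neuron's stimulus-window peak ΔF/F0 is
   triaged into high / moderate / absent with explicit, recorded
   thresholds, replacing by-eye scoring with an auditable rule.
7. **Statistics** — a normality-gated decision tree (Shapiro–Wilk and
   Anderson–Darling, with a large-sample shortcut) that routes two-group
   comparisons to Student/Welch t or Mann–Whitney and multi-group
   comparisons to ANOVA + Bonferroni or Kruskal–Wallis + tie-corrected
   Dunn post hocs, with conventional star labels.

Static-image reporter quantification (polygon or threshold ROIs,
background-subtracted means) and single-plane compartment traces for
light-response streams (anterior neurite / posterior neurite / soma) are
also included.

Because real recordings of this kind are rarely deposited in analyzable
form, the package ships a **synthetic movie generator** whose defaults
mirror the emulated acquisition (128×128 px, 350 frames at 2 s/frame,
stimulus onset at frame 40 for 100 frames, 10–15 Z planes, whole-field
drift and twitches, photobleaching, Poisson shot noise and Gaussian read
noise) and which emits complete ground truth: per-frame shifts, per-neuron
masks, noiseless traces, and true response classes. Every quality claim
the package makes is measured against that ground truth or against
brute-force oracles.

## Worked example

`examples/paired_recording.py` simulates one paired-neuron recording at
full acquisition geometry and runs the complete pipeline:

```
$ python examples/paired_recording.py
movie: 350 frames x 5 planes, 128x128 px, 2.0 s/frame
registration: 100.0% of frames recovered the exact simulated drift (max |shift| 10 px)
 left: class=high     (truth high    ) peak dF/F0=0.899 at +4 s, baseline sigma=0.0204, F0=133.6
right: class=moderate (truth moderate) peak dF/F0=0.320 at +4 s, baseline sigma=0.0200, F0=74.4
```

`examples/batch_classification.py` runs a six-movie batch under two
conditions and prints the per-condition response fractions and pooled
curves:

```
$ python examples/batch_classification.py
response fractions per condition:
 condition  n  n_unclassifiable  n_absent  frac_absent  n_moderate  frac_moderate  n_high  frac_high
   control  6                 0         6          1.0           0            0.0       0        0.0
stimulated  6                 0         0          0.0           0            0.0       6        1.0

pooled control: peak mean dF/F0 = 0.023 at +118 s from onset (n = 6 traces)
pooled stimulated: peak mean dF/F0 = 1.225 at +4 s from onset (n = 6 traces)
```

`examples/static_quantification_stats.py` quantifies reporter images and
walks the statistics tree (here all groups pass the normality gate, so the
omnibus is a one-way ANOVA with Bonferroni-corrected pairwise t tests):

```
omnibus: anova_oneway  statistic=137.77  p=8.44e-13  ****
   control vs induced  student_t: p=2.09e-09 (bonferroni)  ****
   control vs strong   student_t: p=2.82e-09 (bonferroni)  ****
   induced vs strong   student_t: p=2.86e-06 (bonferroni)  ****
```

`examples/light_response_compartments.py` shows the no-tracking
compartment mode for immobilized light-response streams.

## Library quick reference

```python
from wormtrace import (paired_neuron_scene, simulate_movie,   # synthetic data
                       process_movie, run, RunConfig, StageParams,  # pipeline
                       register_movie, train_pixel_classifier,
                       track_movie, extract_trace, normalize_trace,
                       pool_traces, classify_response,
                       quantify_roi, compare_two, compare_many)
```

A thin CLI wraps the same functions:

```
wormtrace simulate | register | segment train/apply | track | run | roiquant | stats
```

`run` writes a results bundle — `traces.csv`, `calls.csv`,
`fractions.csv`, `pooled_<condition>.csv`, per-movie shift/track JSON, and
a `manifest.json` holding the full configuration and seed. Rerunning with
the same configuration reproduces every CSV bit for bit; movies whose
tracking fails are excluded from pooling and listed in the manifest rather
than silently dropped.

## Repository layout

```
src/wormtrace/    library (io, registration, segmentation, tracking,
                  traces, roi, stats, synthetic, pipeline, cli)
tests/            unit + acceptance tests (pytest)
examples/         narrative example scripts (the worked examples above)
scripts/          acceptance benchmark runner
docs/methods.md   models, parameter choices, limitations
```

## Limitations

- Registration estimates whole-field integer translations only; rotation,
  scaling and sub-pixel shifts are out of scope.
- Learned segmentation masks dilate slightly during bright transients,
  which attenuates peak ΔF/F0 by up to ~35 % relative to ground-truth
  masks; classification thresholds operate on the measured (attenuated)
  scale. See docs/methods.md.
- The response classifier is a peak-based triage, not a kinetic model fit.
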