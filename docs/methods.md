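# Methods

## The measurement problem

The pipeline analyses pupillary responses to glare-illusion and halo
stimuli presented at five world-centered locations in a VR display, under
an *active* scene (the observer turns their head toward the stimulus) and a
*passive* scene (the environment turns instead).  Each trial is a 90-Hz
pupil-diameter and gaze trace from 0.2 s before stimulus onset to stimulus
offset at 4 s.  The scientific questions live in three per-trial features —
the maximum pupil constriction latency (MPCL), the early component, and the
late-component AUC — compared across the 2 (scene) x 5 (location) x 2
(pattern) within-subject design.

## Stimulus geometry

All angular extents of the display follow the chord convention
`angle = 2 atan(extent / 2d)` at viewing distance `d = 100` scene units.
This convention reproduces every printed extent-angle pair of the display,
including the eccentric 14.41-unit gradation-center offset (8.24 deg), so
it is applied uniformly.  The gaze-rejection radius is the angular radius
of the central white area: `atan(17.62 / 200) = 5.035 deg`.  One printed
value does not fit any convention we tried: the peripheral stimulus
positions are described as displaced 76.64 units ~ 65 deg, while the chord
formula gives ~42 deg.  The displacement and the nominal 65-deg tilt are
therefore stored as two independent constants and not converted.

## Synthetic experiment generator

The generator defines the study conditions under which the pipeline is
validated.  Per subject and scene it produces the full balanced design
(5 x 2 x `reps_per_cell`, default 15, i.e. 150 trials per scene) in
randomized order, with per-(subject, scene) random substreams derived from
one root seed so any subject's data is independent of how many subjects are
generated.

**Trace model.**  Baseline diameter is Gaussian across subjects
(4.0 +/- 0.3 mm).  After a 0.25-s onset latency, constriction follows a
raised-cosine impulse `h(u) = (1 - cos(pi u / tau_r)) / 2` reaching its
full depth at `tau_r = 0.75` s, then re-dilates exponentially with a 2-s
time constant.  The raised cosine was chosen over sharper impulse shapes
(e.g. a gamma-like `(u/tau_r) e^(1-u/tau_r)`) for two reasons: real PLR
recordings show peak constriction velocity mid-descent, not at onset; and
an impulse whose steepest point sits on the onset kink makes the MPCL — and
with it the early component — unstable under any smoothing, so nothing
downstream could be validated against ground truth.  With the raised
cosine the analytic steepest-constriction time is `latency + tau_r/2`
(0.625 s) and the noise-free pipeline recovers it to the sample.

**Amplitudes.**  Glare trials constrict 0.25 mm, halo trials 0.10 mm
(location modifiers default to zero), keeping the glare-halo contrast at
0.15 mm.  These depths are deliberately moderate: the velocity-rejection
rule thresholds the peak absolute pupil slope at 0.001 mm/ms (1 mm/s), and
a constriction reaching its trough within a second cannot be much deeper
than ~0.3 mm without its own noise-free slope crossing that threshold and
the cascade rejecting every clean trial.  With the defaults the noise-free
peak filtered slope is ~0.52 mm/s, comfortably below threshold, while
realistic noise pushes a minority of trials over it (~5-10% rejected, in
the range of rejection ratios reported for head-mounted eye trackers).

**Noise.**  White Gaussian measurement noise (SD 0.01 mm) plus a slow
AR(1) wander (rho = 0.997 at 90 Hz, marginal SD 0.10 mm).  The slow
component survives the 4-Hz low-pass, so the filter's effect on the
velocity rule is exercised rather than vacuous; its velocity contribution
is small because its spectrum is concentrated well below 1 Hz.

**Artifacts.**  Three injected classes mirror what the cascade must
reject: blink runs (Poisson events, 0.1-0.3 s, pupil set missing and gaze
zeroed, as the device does), sustained step offsets in the pupil signal
(0.3-0.8 mm; steps below ~0.12 mm would be smeared under the velocity
threshold by the 4-Hz filter and are not in the default range), and whole
trial gaze drift of 6-9 deg (beyond the 5.035-deg criterion).  Rates are
configurable per scene but default equal: the data offer no generative
account of why active-scene trials should be noisier, so the generator
does not invent one.

**Ground truth.**  Each trial records its latent amplitude, every injected
interval, and the feature values (MPCL, early, AUC) obtained by applying
the feature definitions to the analytic noise-free trace.  Recovery is
measured against these, i.e. against what was actually injected in the
feature's own units.

**What the generator does not emulate.**  No pupil foreshortening with
gaze angle, no saccades, no luminance adaptation across trials, no
between-subject variation in response amplitude or latency (only baseline
varies), and no physiological scene differences.  Passing tests therefore
show the pipeline's rules behave as specified under controlled conditions,
not that the effect sizes it reports generalize to real recordings: with
no subject-by-pattern variability the pattern F statistics on synthetic
data are far larger than any real experiment would produce.  A second
consequence of the morphology: because the MPCL sits mid-descent, the
late-component AUC (deviations from the MPCL value) nearly cancels between
the remaining descent and the recovery, so the default traces carry little
pattern contrast in AUC — the AUC analysis on synthetic data is close to a
null.

## Preprocessing cascade

Stages run in a fixed order, and every stage is deterministic:

1. **Blink interpolation** — shape-preserving piecewise-cubic Hermite
   (PCHIP) through valid samples; leading/trailing gaps take the nearest
   valid value.  Trials with fewer than 2 valid samples are rejected as
   `insufficient_data` rather than raising.
2. **Baseline correction** — subtract the mean over [-0.2 s, 0); 18
   samples at 90 Hz.
3. **Low-pass filter** — zero-phase (forward-backward) Butterworth, order
   3 per pass, 4-Hz cutoff.  Only the cutoff is prescribed by the analysis
   being reproduced; the realization is ours, so tests assert the DC-gain
   and stop-band properties rather than an exact kernel.
4. **Velocity rejection** — peak absolute slope (second-order central
   differences, the same stencil used for the MPCL; second-order one-sided
   at the endpoints) above 0.001 mm/ms.
5. **PCA-distance rejection** — trials stacked as observations x
   stimulus-window timepoints, mean-centered, projected on PC1/PC2; a
   trial is flagged when its score distance exceeds `mean + 3 SD` of all
   distances.  Two documented switches: scope (`participant`, the default,
   avoids between-subject pupil-scale dominating PC1; or `global`) and
   rule (`mean_plus_sd` vs the uncentered `sd_only` reading).  The
   uncentered rule is not the default because it degenerates whenever
   distances concentrate around a nonzero value — with two noise-free
   response groups all distances are equal, their SD is zero, and every
   trial would be flagged.
6. **Gaze rejection** — Euclidean norm of the *mean* gaze offset over
   [0, 4] s above 5.035 deg; a trial that fixates on average but makes
   large excursions is retained, per the mean-based definition.
7. **Participant exclusion** — strict `ratio > 0.30` of rejected trials.

The PCA stage is the one stage whose decision depends on other trials;
adding an artifact to one trial can therefore change PCA flags elsewhere
(the threshold is data-dependent), which is documented rather than fixed.

## Features

* **Slope** — `(x[i+1] - x[i-1]) / 2dt` inside, second-order one-sided at
  the ends (exact for quadratics; empirically O(dt^2) convergent).
* **MPCL** — time of the most negative slope in (0, 1] s; exact ties break
  to the earliest sample (with a 1e-9 relative tolerance so analytically
  tied slopes resolve deterministically).  A minimum slope shallower than
  -0.05 mm/s raises a weak-constriction warning; such trials are flagged
  but retained, since the procedure being reproduced specifies no such
  rejection.
* **Early component** — mean baseline-corrected diameter over
  [MPCL - 0.1 s, MPCL + 0.1 s], inclusive endpoints (19 samples at 90 Hz),
  truncated at trace bounds.
* **AUC** — `sum(x_i - x_MPCL)` from the MPCL sample through the last
  sample at or before 4 s, interpreted on the sample grid (an
  integer-seconds reading would discard nearly all data).  The value is a
  plain sample sum in mm by default; `auc_scale_dt` multiplies by dt for
  an mm*s convention.
* **Mean vertical gaze** — arithmetic mean of y-offset over [0, 4] s,
  valid samples only.

## Statistics

Cell means are computed trial -> subject-cell -> condition, the
conventional aggregation order.  Subjects with any empty cell are dropped
listwise and logged.

The three-way repeated-measures ANOVA decomposes each effect against its
own effect-by-subject interaction; partial eta^2 is
`SS_effect / (SS_effect + SS_error)`.  Sphericity is assessed per effect
by Mauchly's chi-square approximation on the covariance of orthonormalized
(Helmert) effect contrasts — Kronecker products of the per-factor contrast
bases for interactions.  The Greenhouse-Geisser factor
`eps = tr(S)^2 / (d tr(S^2))`, clamped to [1/d, 1], rescales both degrees
of freedom whenever Mauchly's p < 0.05 for that effect; uncorrected values
are always reported alongside, and the exactness of Mauchly's test at very
small n is not pursued.  One-degree effects have eps = 1 and no sphericity
test.  A zero-variance error term yields F = NaN, reported as such.

Post hoc paired t-tests collapse the other two factors to subject-level
means, apply Holm-Bonferroni within the factor's pairs, and report both
Cohen's d conventions (`d_z` = mean diff / SD of diffs; `d_av` = mean diff
/ average level SD) as columns rather than guessing between them — the two
conventions disagree in published post hoc tables often enough that the
choice belongs to the reader.  Identically-zero differences report
t = 0, p = 1, d = 0; zero-variance nonzero differences report NaN.

## Calibration studies and problem sizes

Type-I error and power are assessed at the cell-mean level with a direct
simulator (subject intercept SD 0.3 mm + within-subject cell noise SD
0.08 mm), which is what the trial-level generator induces after
aggregation and makes thousands of replicate ANOVAs a desk-scale
computation: 1000 18-subject null replicates per feature for the 5%
rejection-rate check, and 200 replicates with a 0.15-mm pattern effect for
power (the paired effect size d_z ~ 1.9 makes power essentially 1 at
n = 18).  Trace-level parameter recovery uses small noise-free experiments
(2-3 subjects, 2 repetitions per cell), where the pipeline's estimates
must match the analytic ground-truth features; the residual there is
filter distortion alone.

## Numerical choices

* Time grids are stored explicitly and validated to 1e-9 s; dropped frames
  surface as format errors rather than silent resampling.
* Window membership uses half-sample-scaled tolerances so on-grid
  endpoints are included deterministically.
* The device's meter-unit pupil column is converted to mm on read; raw
  diameters outside (0.5, 10) mm warn (they are not errors, and the check
  is suppressed for baseline-corrected traces whose median is near zero).
* CSV round-trips are bit-exact: floats are written at 17 significant
  digits and parsed with round-trip precision.

## Known limitations

* The velocity threshold of 0.001 mm/ms is below the peak constriction
  velocity of a typical real PLR (~3-6 mm/s); applied literally to real
  recordings it would reject most trials.  The pipeline implements the
  rule as stated; the generator's amplitudes are chosen so that clean
  synthetic trials pass it.  Analysts applying this pipeline to real data
  should expect to raise the threshold.
* Bayesian model-averaged ANOVA (Bayes factors) is out of scope; the
  report deliberately has no BF columns.
* No correction for pupil foreshortening, no saccade handling, no
  eye-tracker calibration model.
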