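# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `cardioaudio`, and what the synthetic test bed does and
does not establish about real data.

## The paradigm being modeled

Tones are triggered in real time by the listener's heartbeat and follow
the triggering R-peak by, on average, 287 ms ("perceived synchronous") or
587 ms ("perceived asynchronous"); the trigger-to-sound interval carries
a 30-ms jitter (SD) from the online detection chain. Trials contain 7–10
tones; in half of the trials the third-from-last tone is omitted. A cue
directs attention either to the heartbeat–sound relationship (internal
task: "were the tones synchronous with your heart?") or to the sounds
alone (external task: "was there a missing tone?"), answered yes/no with
1–4 confidence. A session is 4 blocks × 56 trials with all
attention × delay × omission cells balanced (28 each) and no more than 3
consecutive trials of the same attention × delay condition; intertrial
intervals are uniform 2–3 s. The analysis centers on the heartbeat-evoked
potential (HEP) around omitted sounds: evoked activity at the moment a
heartbeat-predicted tone fails to occur.

## Synthetic data generator (`synthgen`)

Every output is a pure function of `(config, seed)`; per-subject streams
are derived through `SeedSequence([seed, subject])`, so regenerating a
study is byte-identical.

**ECG.** R-peak times accumulate interbeat intervals drawn from a normal
distribution (default 0.8 ± 0.05 s) truncated at ±3 SD. Each beat places
a fixed P-QRS-T template (sums of Gaussians; R amplitude 1 mV) into two
leads of opposite polarity with 0.02 mV sensor noise. The returned peak
list is exact ground truth.

**EEG** (µV) is a sum of:

- 1/f^α background noise (α = 1 by default, spectral synthesis) scaled to
  5 µV per channel, plus a 1 µV white floor;
- a cardiac field artifact: the noise-free cardiac trace times a
  per-channel gain map (default 8 µV/mV, left-inferior dominant with a
  sign flip across the midline — enough spatial structure to exercise the
  correction, with no claim of biophysical realism);
- a heartbeat-locked evoked component (1 µV Gaussian bump, 300 ms
  post-R, 50-ms width) under a central topography;
- a tone-evoked N1–P2-like biphasic deflection (4 µV) after every tone;
- the condition-dependent omission-locked component: by default a 4 µV
  bump spanning 95–138 ms after the scheduled onset of the omitted sound,
  injected **only in the internal-attention, short-delay cell** (fully
  configurable via `omission_effect_uv`);
- optional frontal biphasic blink transients at Poisson times and
  noise-swamped bad channels.

Amplitude and noise defaults were chosen once as field-typical values
such that the injected omission effect is recoverable by the pipeline at
study scale but invisible in single trials (single-trial SNR ≈ 0.8/5);
they are deliberately "neither trivial nor hopeless".

**Behavior** comes from an equal-variance Gaussian SDT model: on internal
trials the signal class is the short delay (population d′ defaults to
0.218, the weak group-level heartbeat-discrimination sensitivity typical
of this task), on external trials the omission (d′ = 3.091). Confidence
is the distance of the evidence — corrupted by metacognitive noise
(SD 0.3) — from the criterion, cut at thresholds (0.5, 1.0, 1.5).

**Layouts** are sunflower-spiral discs. The disc radius (0.46) was fixed
so that the 128-channel layout reproduces the neighborhood statistics of
the dense BioSemi-style montage the analysis conventions assume: median
degree 11 at the 0.15 adjacency distance (our range is 5–15; a real
montage is more irregular at the rim).

What the generator does **not** emulate: volume-conducted spatial noise
correlations (channels are independent except through injected
components), respiration and movement artifacts, heart-rate reactivity to
stimuli, non-stationary arousal drifts, and any biophysical head model.
Passing tests therefore establish the *statistical machinery* —
detection, correction, inference — not montage-specific effect sizes on
real recordings.

## Cardiac event chain (`cardiac_events`)

The **online detector** recreates the real-time trigger: the variance of
the preceding 33-ms window (17 samples at 512 Hz, inclusive of the
current sample) is compared against an individually calibrated threshold;
a 250-ms refractory period — safely below the 0.4-s minimum plausible
IBI — suppresses re-triggering. Calibration (the published procedure
leaves this open) takes the midpoint between the 95th percentile of
baseline window variance (> 100 ms from any beat) and the median per-beat
peak variance over a ≥ 10-s segment; being a variance, it scales
quadratically with signal gain.

The **offline detector** is a classic energy pipeline: 5–30 Hz band-pass,
squared derivative, 150-ms moving-window integration, peak picking with a
250-ms minimum distance above an adaptive threshold (20% of the 99th
percentile), then refinement to the R maximum of the dominant polarity in
a ±60-ms window — hence polarity-robust.

Block QC rejects a block if any within-block R–R interval exceeds 1.5 s
or falls below 0.4 s (the signature of missed/doubled online triggers).
Post-omission intervals are labeled "omission to 1" (triggering R-peak to
next beat) and "1 to 2" (the following interval); "baseline" is the
interval ending at the trigger.

## Preprocessing (`hep_preprocess`)

Stage order: band-pass filter (EEG 0.5–40 Hz, ECG 0.5–150 Hz) → epoch
(−300 to +800 ms, half-open on the sample grid, so the standard window is
exactly 563 samples at 512 Hz) → mastoid reference → three-stage
rejection cascade → ICA cleanup → spherical-spline interpolation of
removed channels → whole-head average reference → heartbeat-locked CFA
subtraction → robust averaging → 20-Hz low-pass. **No baseline
correction** anywhere: cardiac activity is cyclical, and pre-event
baselines contain structured signal that would alias into post-R effects.

Filters are windowed-sinc Hamming FIRs applied high-pass-then-low-pass;
transition bandwidths are max(0.25·f, 0.25 Hz) for the high-pass and
min(0.25·f, 10 Hz) for the low-pass; odd-length symmetric kernels applied
by centered convolution after reflection padding give exact zero phase.

The cascade z-scores three metrics per stage across the scanned axis and
flags |z| > 3 on any metric: raw channels (variance, mean absolute
inter-channel correlation, Hurst exponent), trials (channel means of
voltage range, variance, and deviation of the trial mean from the
all-trial mean), ERP-level channels (variance, median absolute gradient,
range across time). Zero spread on a metric defines z = 0 (degenerate but
valid inputs flag nothing). The Hurst estimator uses discrete
second-order differences at dyadic lags: H = ½·log₂(S₂/S₁), which is
exact in expectation for fractional Brownian motion; an exactly linear
input is degenerate and returns the upper boundary with a warning.

Stationary-artifact removal runs FastICA at full channel rank and scores
components on frontal topography dominance (> 0.45 of absolute weight
above y = 0.25), low-frequency power share (< 5 Hz, > 0.5), and excess
kurtosis (> 3); components meeting all three look like blinks and are
subtracted. The classifier is a pluggable callable (and `None` is an
identity transform); the thresholds are heuristics tuned for the
generator's blink model, not a port of any published feature set.

Spherical-spline interpolation maps the 2-D layout onto the sphere by
inverse azimuthal projection (rim at polar angle 120°) and solves the
standard spline system with order m = 4, Legendre truncation l ≤ 7, and
10⁻⁵ diagonal regularization.

CFA correction subtracts a resting heartbeat-locked template — computed
from the pre-task rest period through the same referencing path — at
**every** heartbeat latency recorded in each epoch, truncated at epoch
edges. Because the resting template contains both the cardiac field
artifact and the stereotyped HEP, this also removes the HEP-latency
confound when omission-locked windows at different post-R delays are
compared (the generator demonstrates exactly this confound when the
correction is disabled).

Robust averaging reweights per (channel, time) point: residuals from the
current weighted mean are scaled by 1.4826 × the median absolute
deviation across epochs; Huber weights (tuning constant k = 3 robust-SD
units) are iterated to a 10⁻⁶ change tolerance, at most 50 iterations
(non-convergence returns the last iterate and logs a warning). With no
outliers all weights remain 1 and the result equals the arithmetic mean;
a single gross outlier's influence is bounded by k·s.

## Cluster statistics (`cluster_stats`)

Sensor adjacency: channel pairs closer than 0.15 in layout units.
Pointwise two-tailed t-maps (paired or pooled-variance independent) are
thresholded at p < 0.05, suprathreshold points are connected through
spatial adjacency at the same sample and temporal contiguity within a
channel, split by t sign. A cluster is kept only if it spans ≥ 2 samples
and ≥ 4 distinct channels. The published "at least 4 neighboring
electrodes" rule is ambiguous between this cluster-extent reading
(default) and a per-point neighbor count; the latter is available as
`neighbor_rule="minnbchan"`.

The null is the distribution of the maximum |mass| over permutations:
per-subject condition swaps (sign flips of the difference maps) for
paired designs — the subject is the exchangeable unit for group
inference — and group-label shuffles for independent designs. Cluster
p = (b + 1)/(n + 1), which is a valid finite-sample p; when the complete
permutation set has ≤ 2¹⁴ elements it is enumerated instead and the
identity permutation makes the +1 unnecessary (p = b/N).

The interaction is the double subtraction
(short − long)internal − (short − long)external tested against zero;
on rejection, short vs long is tested within each attention level.
Analysis windows: 0–229 ms post-R for R-locked contrasts (the first
percentile of short-delay R-to-sound intervals — on new data this
percentile should be recomputed, not assumed) and 0–213 ms after the
scheduled omitted-sound onset (= 287–500 ms and 587–800 ms post-R for
short/long) for omission-locked contrasts.

ECG control contrasts run through the identical code path with the
two-lead ECG epochs substituted, but with minimum cluster extent 1
channel: two sensors can never satisfy the 4-channel rule, which would
make the control vacuous by construction.

## Cardiac dynamics and Bayes factors (`cardio_dynamics`)

Repeated-measures ANOVAs are computed from per-subject contrast scores:
every effect in a fully-within design of 2-level factors has one
numerator df and equals a one-sample t-test on the contrast (F = t²),
with partial η² = F·df₁/(F·df₁ + df₂); the implementation is
cross-checked against an independent ANOVA routine for the two-factor
case. Post-hoc paired comparisons default to the t-test and switch to the
Wilcoxon signed-rank test when Shapiro-Wilk rejects normality of the
differences at α = 0.05 (the published switching rule is unstated; both
statistics are always reported). SDRR is the n−1 standard deviation of
within-condition IBIs.

Bayes factors are the common defaults: the JZS t-test Bayes factor with a
Cauchy(0, 0.707) effect-size prior, computed as a noncentral-t mixture by
adaptive quadrature (relative tolerance 10⁻⁹; df = n − 1 with effective
size n for one-sample/paired, df = n₁ + n₂ − 2 with n₁n₂/(n₁+n₂) for
independent); and the two-sided correlation Bayes factor from the exact
sampling density of r under a stretched-beta(1/κ, 1/κ) prior with κ = 1.
These choices reproduce the published values of all five recomputable
statistics to well under 1%. Model-averaged "inclusion" Bayes factors
from Bayesian-ANOVA model spaces are out of scope.

## Pipeline and problem sizes

`pipeline.run_pipeline` applies the stages above per subject, excludes
subjects losing more than a third of their omission trials, stacks
condition-wise robust averages, and writes TSV/JSON results with a config
digest and seed in the log. The YAML config mirrors the defaults above.

The simulation-based validation suite uses deliberately scaled problem
sizes chosen by design calculation: permutation-test error calibration on
16 subjects × 8 channels × 50 samples × 1000 permutations × 200 null
datasets, with spatio-temporally correlated Gaussian noise (spatial
correlation exp(−d), temporal Gaussian smoothing σ = 5 samples) — with
white noise the cluster-formation probability is so low that the
calibration check is uninformative; and end-to-end power on 25 studies of
10 subjects, 16 channels, 4 × 24 trials, 5–6 tones per trial, adjacency
distance 0.25, 500 permutations, with the generator's effect and noise
defaults untouched. The integration test runs 4 subjects at 2 × 16
trials. Full-scale configurations (34 subjects, 128 channels, 224 trials)
are the generator defaults and run unchanged, just longer.

## Known limitations

- The ICA component classifier is a three-feature heuristic; published
  artifact-classification feature sets are not ported (the classifier is
  pluggable for that purpose).
- Robust-averaging numerics approximate, not replicate, any specific
  toolbox's implementation.
- The correlation Bayes factor's exact-density route needs |r| < 1 and
  n ≥ 4; the meta-d′ fit requires non-degenerate type-1 behavior
  (|d′| > 10⁻⁸ for a defined M-ratio).
- EDF round-trips are exact only to one 16-bit quantization step of each
  channel's physical range.
- Extreme-rate (1/(2N)) and sparse-cell (1/(2·cells)) corrections in the
  SDT fits are conventions; analyses of borderline subjects can differ
  across convention choices.
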