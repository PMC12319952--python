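# Methods

`attnpipe` implements, end to end, the analysis of a color-coherence
detection experiment that probes how many attentional templates can be held
active at once: observers are cued with one to three colors (or none), then
judge whether a 240-dot field contains an over-representation of a cued
color. The package covers the task design, a synthetic EEG/behavior
generator, EEG preprocessing, univariate (ERP, alpha power) and multivariate
(temporal decoding) analyses, and the inferential statistics, so that every
group-level statistic of such a study has a desk-scale synthetic analogue.

## Stimulus model

Color coherence is the proportion `P_t` of dots sharing the target color.
With the four non-target display colors at equal proportion `P_n`,

    coherence = P_t = 1 - 4 * P_n,

so a pure-noise field has coherence 0.2 (all five proportions equal) and 1.0
is a single-color field. `compose_dot_field` converts a coherence level to
integer dot counts by largest-remainder apportionment: floor all ideal
counts, then assign leftover dots by descending fractional part (target color
first on ties). This guarantees the counts sum to `n_dots` exactly while
never deviating from any ideal count by a full dot.

Display-color selection enforces the design's key constraint: the target
color always appears; cued-but-non-target colors never appear; the remaining
four display colors are drawn uniformly without replacement from the
non-cued remainder of the 7-color palette.

## Schedules

* Practice: 2 superblocks, each a random order of the four cue conditions,
  8 blocks x 84 trials, 75% target / 25% noise, cue-to-stimulus interval
  fixed at 0.8 s. Yields 168 trials per condition (126 target + 42 noise).
* EEG: 10 alternating one-cue/two-cue blocks x 84 trials, cue-to-stimulus
  interval uniform in [0.8, 1.1] s. Color marginals are exact by
  construction (9 target + 3 noise trials per color per block), giving 45
  target and 15 noise trials per color per condition.
* Timing: stimulus onset = cue onset + 0.5 s (cue display) + the
  cue-to-stimulus interval. Trial spacing adds a 0.15 s stimulus, a 1.5 s
  response window and a 1.0-1.5 s inter-trial interval, so a cue-locked
  [-0.5, 3] s epoch never overlaps its neighbors.

Design choices where the design was genuinely open: no-cue trials draw their
target color uniformly from the 7-color palette; cue positions are stored as
metadata only (uniform random rotation, maximal angular separation); trial
`coherence` defaults to 0.44 on target trials (the group-mean threshold) and
0.2 on noise trials.

## Adaptive staircase

The threshold procedure interleaves seven 2-down-1-up staircases (one per
color) across 5 runs of 84 trials: 12 trials per color per run, 9 target + 3
noise, hence 60 trials per staircase of which the 45 target trials update the
level (noise trials carry no coherence to adjust). Step size 0.04, start
0.8, coherence clamped to (0.2, 1.0] with the working floor at 0.2 + step.
The rule converges on the sqrt(0.5) ~ 70.7%-correct point. The threshold
estimate is the mean of the last 4 reversal levels, which discards the
initial descent from the 0.8 starting level; in simulation this estimator's
bias against the analytically inverted 70.7% point is ~0.02 coherence units
(well inside the 0.05 recovery tolerance), where averaging all reversals
is biased upward by ~3x that. A staircase that pins at coherence 1.0 is
flagged non-converged, mirroring the participant-exclusion rule.

## Synthetic EEG generator

The generator emulates exactly the statistical structure the analyses
assume, not biophysics:

* Background: Gaussian 1/f^a noise (default a = 1, scale 10 uV), shaped in
  the frequency domain.
* Alpha: a ~10 Hz narrowband process (default 5 uV) weighted onto the 17
  posterior electrodes, multiplied by an envelope that dips (default depth
  0.5) for ~1 s after every visual onset (cue display, dot field) —
  event-related alpha suppression.
* Color patterns: per subject and color, a fixed unit-norm channel weight
  vector concentrated on the posterior cluster (non-posterior scale 8% of
  posterior), redrawn deterministically if any pairwise |cosine| reaches
  0.95, so the 7 patterns are mutually non-collinear and colors are linearly
  decodable in principle.
* Target response: on target trials the target color's pattern is added as a
  Gaussian bump (peak 300 ms post-stimulus, FWHM 100 ms) with amplitude
  `g_k * (coherence - 0.2)`: the attention gain `g_k` (defaults 30/15/10 uV
  per unit coherence-excess for one/two/three cues, 0 for no cue) times the
  coherence signal above the noise floor — a noise field carries nothing to
  decode. The one > two gain ordering is the generative claim under test
  downstream.
* Cue response: each cued color's pattern appears during the cue display
  (total energy fixed: gain is split across cues), and persists at 15% gain
  through the preparatory period. The preparatory strength is deliberately a
  free parameter: real preparatory-period effects are subtle and the
  generator does not pretend to constrain them.
* Artifacts: optional Poisson blink events (frontal pattern, ~300 uV+)
  for exercising rejection; off by default.

The observer models mirror the two candidate accounts of the template limit:
*weakened-template* applies a sensitivity multiplier `s_k` (defaults
6.4/5.2/3.5/3.0 for one/two/three/no cues, chosen so one-cue hit rate ~0.9
and false-alarm rate ~0.4 at threshold coherence with unit evidence noise
and criterion 0.25); *switching* attends a single cued color per trial
(uniform), using the one-cue strength when the attended color is the one
present and the no-cue strength otherwise. Evidence is
`s_eff * (coherence - 0.2) + N(0, 1)`; response "target" iff evidence exceeds
the criterion; RT = base 0.4 s + 0.4 s * exp(-|evidence - criterion|), times
lognormal noise — faster when evidence is far from the criterion.

What the generator does **not** emulate: realistic ERP component morphology,
eye movements, channel covariance structure of real scalp EEG, non-stationary
impedance drifts, or per-condition criterion shifts (so false-alarm rates do
not differ across conditions unless strengths do). Passing tests therefore
demonstrate that the *analysis code* behaves correctly under controlled
statistical structure, not that real EEG would yield these effect sizes.

## Preprocessing

Order is fixed: re-reference (mean of TP9/TP10) -> band-pass + notch ->
epoch + baseline -> amplitude-threshold rejection -> optional resampling.
The band-pass is implemented as separate 2nd-order Butterworth high-pass
(0.01 Hz) and low-pass (80 Hz) applied zero-phase, giving half-amplitude
(-6 dB) at the nominal cutoffs and 12 dB/octave per pass direction; the
notch is a 2nd-order 58-62 Hz band-stop (contract: >= 20 dB at 60 Hz). By
default the zero-phase response is applied in the frequency domain (exact
squared-magnitude response, no filtfilt edge transients — relevant because a
0.01 Hz pole's settling time exceeds short test fixtures); `method="sos"`
provides the classical forward-backward implementation.

Epochs: cue-locked [-0.5, 3.0] s with baseline [-0.5, 0]; target-locked
[-2.1, 1.4] s with baseline [-2.1, -1.6] (the pre-cue interval, given the
jittered cue-to-stimulus delay). Rejection removes any trial with |V| >
200 uV on any channel within [-0.5, 2] s (clipped to the epoch), computed
from voltages only — label-blind by construction. Blink removal by ICA is
out of scope: there is no deterministic criterion to reproduce, so the
threshold rule is the only cleaning step (an amplitude-gradient criterion
could be added, but is off by default).

## ERP and time-frequency analysis

ERPs average target trials, then the 17 posterior electrodes (Pz, P1-P8,
POz, PO3/4, PO7/8, Oz, O1/2); statistics run on the electrode-averaged
waveform. Spectral power uses 60 Gabor wavelets, log-spaced 2-80 Hz, with
spectral SD sigma_f = f/5 (about 5-cycle atoms) and unit-energy
normalization; power is computed per trial and trial-averaged (total power).
The exact wavelet parameters of the toolchain this emulates are not public;
the bank is therefore configurable and the defaults above are stated rather
than guessed further. dB normalization uses a *common* baseline: baseline
power (time-averaged, default [-0.5, 0] s) is averaged across conditions per
frequency, each condition is divided by it, and 10*log10 applied — so a
condition equal to the common baseline is exactly 0 dB and the measure is
invariant to global amplitude rescaling. Alpha is 8-14 Hz.

## Decoding

Features are the 17 posterior channels, resampled to 100 Hz, low-passed at
15 Hz (4th-order zero-phase Butterworth) and Gaussian-smoothed (FWHM 20 ms).
At every time point a multiclass LDA (uniform priors, pooled within-class
covariance with ridge 1e-6 * trace/p for invertibility) is trained and
tested under stratified 5-fold cross-validation: each class's trials are
split across folds, surplus trials retained. The whole procedure repeats
over 10 independently re-partitioned iterations (2 in the desk profile) and
averages; accuracies are then smoothed with a centered 40 ms moving mean
whose window shrinks at the edges. Chance is 1/7. Two-cue cue-color decoding
runs two passes — labels = first (target) cue, labels = second cue — with
separate classifiers, and averages the two accuracy series. Fold assignments
are a pure function of the supplied rng, making every decoding run
reproducible; seeds are first-class outputs of the pipeline report.

## Statistics

* Cluster-based permutation tests (paired, and one-sample vs chance):
  per-sample t, cluster-forming threshold at two-tailed p < 0.05, cluster
  mass = sum of t within a run (positive/negative runs separate), null =
  per-subject sign flips summarized by max |mass|. For n <= 12 subjects all
  2^n flips are enumerated (p = exceedances / 2^n, identity included, never
  zero); otherwise a seeded Monte-Carlo sample with the
  (1 + exceedances)/(1 + permutations) estimator. Sum-of-t mass was chosen
  over sum-of-t^2 as the conventional default; zero-variance samples are
  excluded from cluster formation with a warning.
* One-way repeated-measures ANOVA by direct sum-of-squares decomposition;
  partial eta squared = df1 F / (df1 F + df2).
* Paired t-tests with Cohen's d = t / sqrt(n) — this definition reproduces
  reported d values exactly, where mean/SD-of-differences variants differ in
  the second decimal.
* Signal detection: log-linear correction (0.5 per cell, 1 per denominator),
  d' = z(H) - z(FA), criterion = -(z(H) + z(FA))/2. The correction is a
  determinism choice; uncorrected rates are available via `sdt_from_rates`.
* Within-participant SEM: Cousineau normalization (remove subject means, add
  grand mean) with the Morey sqrt(k/(k-1)) correction.
* Brain-behavior: Pearson r between per-subject hit-rate difference
  (one-cue minus two-cue) and decoding-accuracy difference, averaged over
  the preparatory window (0.5-1.25 s post-cue) or the stimulus window
  (target onset to the subject's condition-specific median hit RT); p uses
  n - 2 df.

## Pipeline profiles and problem sizes

The `desk` profile (default) runs 12 subjects, 500 permutations and 2
decoding iterations; `full` mirrors the study scale (28 subjects, 10,000
permutations, 10 iterations). The desk-scale experiment recipes in
`attnpipe.experiments` choose sizes the same way: chance decoding simulates
the one-cue half of the session for 12 subjects (45 target trials per color
is a per-condition count, so the two-cue half adds nothing to that check);
cluster-test calibration uses 200 null datasets of 20 subjects x 100 time
points at 500 permutations; the gain-contrast experiment simulates 20 full
sessions with a fixed 2:1 one-cue:two-cue gain ratio and per-subject gain
scale (SD 0.25) coupled into the observer's one-cue sensitivity, which
yields the sign-test contrast and the brain-behavior correlation from a
single cohort; staircase recovery runs 100 replicate threshold sessions.

## Numerical notes and limitations

* Records are synthesized in float32; epochs are promoted to float64 so
  baseline residuals sit at machine precision relative to signal scale.
* The LDA ridge (1e-6 * trace/p) is a numerical guard, not a tuned
  shrinkage; with 17 features and >= 36 training trials per fold the pooled
  covariance is comfortably full rank.
* Unit-energy wavelets weight a flat-amplitude input toward lower
  frequencies (response scales with sqrt(sigma_t)); band-averaged dB values
  are unaffected because the baseline shares the weighting.
* Cluster p-values are valid but conservative near the floor 1/2^n in
  exhaustive mode; with 5 subjects the smallest attainable p is 1/32.
* The behavioral observer has a fixed criterion across conditions, so
  condition effects appear in hit rates but not false-alarm rates unless
  template strengths differ; real observers also shift criteria.
* `run_full_pipeline` aborts naming the failing stage and keeps partial
  TSV outputs.
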