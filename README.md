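# attnpipe

Behavioral + EEG analysis pipeline for **multi-color feature-attention
experiments**, built around a color-coherence detection task: observers are
cued with one to three colors (or none) and judge whether a 240-dot field
contains an over-representation of a cued color. The scientific question is
how many *attentional templates* can be held active at once; the signatures
are worse detection and weaker EEG color decoding as the number of cued
colors grows, and a brain-behavior correlation between the two effects.

The package is aimed at cognitive/EEG researchers who want the full analysis
chain as tested, reusable code — including a synthetic-data generator, so
every stage runs and is verifiable without any recordings.

## What it implements

* **Task design** (`attnpipe.task_design`) — dot-field composition from the
  coherence model `coherence = P_t = 1 - 4 P_n` (0.2 = pure noise), display
  color selection (cued-but-non-target colors never shown), practice and EEG
  trial schedules with exact condition/color marginals, and interleaved
  2-down-1-up staircases converging on the 70.7%-correct coherence.
* **Synthetic data** (`attnpipe.synthetic`) — 64-channel records at 500 Hz:
  1/f background, posterior alpha with event-related suppression, subject-
  specific color topographies whose evoked amplitude scales with an attention
  gain `g_k` (decreasing in the number of cues) and the coherence signal
  above the noise floor; plus two behavioral observer models
  (weakened-template vs single-template-with-switching).
* **Preprocessing** (`attnpipe.preprocessing`) — TP9/TP10 re-referencing,
  zero-phase Butterworth band-pass (0.01-80 Hz, half-amplitude cutoffs,
  12 dB/octave) + 60 Hz notch, cue-locked/target-locked epoching with
  baselining, 200 uV artifact rejection, polyphase resampling, BrainVision
  and HDF5 I/O.
* **ERP / time-frequency** (`attnpipe.erp_tfr`) — posterior-17 ERPs; 60
  log-spaced Gabor wavelets (2-80 Hz, ~5 cycles), common-baseline dB
  normalization, alpha-band (8-14 Hz) time courses.
* **Decoding** (`attnpipe.decoding`) — per-timepoint 7-class LDA (pooled
  covariance + minimal ridge) on the posterior channels at 100 Hz, stratified
  5-fold cross-validation, iteration averaging, 40 ms smoothing; chance =
  1/7; two-cue cue-color decoding decodes each cue separately and averages.
* **Stats** (`attnpipe.stats`) — cluster-based permutation tests (sign-flip
  null, max cluster mass, exhaustive for n <= 12), repeated-measures ANOVA
  with partial eta squared, paired t with d = t/sqrt(n), d'/criterion with
  log-linear correction, within-participant SEM (Cousineau-Morey), Pearson
  brain-behavior correlation.
* **Pipeline** (`attnpipe.pipeline`, CLI `attnpipe`) — end-to-end runs from
  a single config with TSV/JSON outputs and full seed control.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

Simulate and analyze a small cohort end to end (5 subjects, full 840-trial
sessions, desk-scale statistics):

```bash
attnpipe run --subjects 5 --seed 7 --out demo_out
```

prints (abridged to 3 decimals):

```json
{
  "behavior": {
    "one": {"hit_rate": 0.880, "fa_rate": 0.419, "hit_rt_median": 0.514,
            "cr_rt_median": 0.583, "dprime": 1.391},
    "two": {"hit_rate": 0.836, "fa_rate": 0.389, "hit_rt_median": 0.531,
            "cr_rt_median": 0.608, "dprime": 1.259}
  },
  "brain_behavior": {
    "stimulus": {"r": 0.855, "p": 0.065},
    "preparatory": {"r": 0.484, "p": 0.409}
  }
}
```

Reading the numbers: hit rates are high (~0.88) and false alarms substantial
(~0.4) because targets appear on 75% of trials at threshold coherence —
detection is genuinely hard. The one-cue condition shows more hits, faster
responses and higher d' than two-cue (the attentional-template cost), and
subjects with a larger one-minus-two decoding difference in the stimulus
window also show a larger hit-rate difference (positive stimulus-window r;
with only 5 subjects the correlation is unstable and p stays above 0.05).
`demo_out/` contains the TSV twins (behavior, ERP, alpha power, decoding
accuracy, brain-behavior table) plus `report.json` with cluster tests,
rejection rates, timings and seeds.

Library use follows the same stages:

```python
import numpy as np
from attnpipe.task_design import build_eeg_schedule
from attnpipe.synthetic import GeneratorParams, simulate_session
from attnpipe.pipeline import preprocess_session
from attnpipe import decoding as dec

rng = np.random.default_rng(0)
schedule = build_eeg_schedule(rng)
record = simulate_session(GeneratorParams(subject_seed=1), schedule, rng)
epochs = preprocess_session(record, schedule)["target"]
prepared = dec.prepare_for_decoding(epochs)          # posterior 17, 100 Hz
target_only = prepared.select_trials(prepared.trial_meta.is_target.astype(bool))
result = dec.temporal_decode(target_only, rng=np.random.default_rng(1))
```

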