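"""Desk-scale simulation experiments: calibration and parameter-recovery checks.

Each function runs the *actual* pipeline (schedule -> synthetic record ->
preprocessing -> decoding -> statistics) at a size that completes in minutes
on one CPU, and returns the quantities a reader would check against the
study-scale expectations: chance-level decoding on signal-free data, the
family-wise error rate of the cluster permutation test under the null, the
one-cue > two-cue decoding contrast when the generator's attention gains
actually differ, the induced brain-behavior correlation, and 2-down-1-up
staircase threshold recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from . import decoding as dec
from . import stats
from .pipeline import RunConfig, behavioral_summary, preprocess_session, subject_params
from .synthetic import (GeneratorParams, psychometric_observer, simulate_observer,
                        simulate_session)
from .task_design import (build_eeg_schedule, run_threshold_session,
                          two_down_one_up_convergence_point)

EVOKED_WINDOW = (0.15, 0.45)  # s post-target, around the evoked-bump peak


def _decode_target_conditions(epochs, k, iterations, rng):
    prepared = dec.prepare_for_decoding(epochs)
    tgt = prepared.select_trials(prepared.trial_meta["is_target"].to_numpy().astype(bool))
    out = {}
    for cond in sorted(set(tgt.trial_meta["cue_condition"])):
        sub = tgt.select_trials((tgt.trial_meta["cue_condition"] == cond).to_numpy())
        res = dec.temporal_decode(sub, k=k, iterations=iterations, rng=rng)
        out[cond] = dec.smooth_accuracy(res)
    return out


@dataclass
class ChanceDecodingResult:
    per_subject: np.ndarray      # mean accuracy per subject (post-target window)
    grand_mean: float
    se: float
    chance: float = 1.0 / 7.0


def chance_decoding(n_subjects: int = 12, seed: int = 0, k: int = 5,
                    iterations: int = 2) -> ChanceDecodingResult:
    """Full decoding pipeline on signal-free records (45 target trials/class).

    Simulates one-cue sessions whose generator carries background noise and
    alpha but no color-specific signal, then decodes target color from the
    target-locked epochs. The grand-mean accuracy estimates the empirical
    chance level (expected: 1/7).
    """
    per_subject = []
    for s in range(n_subjects):
        rng = np.random.default_rng([seed, s, 21])
        schedule = build_eeg_schedule(rng, conditions=("one",))
        gen = GeneratorParams(
            evoked_gain={"no": 0.0, "one": 0.0, "two": 0.0, "three": 0.0},
            cue_signal_gain=0.0,
            subject_seed=int(rng.integers(2**31)),
        )
        record = simulate_session(gen, schedule, rng)
        epochs = preprocess_session(record, schedule, locks=("target",))
        del record
        res = _decode_target_conditions(epochs["target"], k, iterations,
                                        np.random.default_rng([seed, s, 22]))["one"]
        mask = (res.times >= 0.0) & (res.times <= 1.0)
        per_subject.append(float(res.accuracy[mask].mean()))
    arr = np.array(per_subject)
    return ChanceDecodingResult(arr, float(arr.mean()),
                                float(arr.std(ddof=1) / np.sqrt(len(arr))))


@dataclass
class CueingGainResult:
    acc_one: np.ndarray          # evoked-window accuracy, one-cue, per subject
    acc_two: np.ndarray
    hit_one: np.ndarray
    hit_two: np.ndarray
    stim_decoding_diff: np.ndarray  # stimulus-window accuracy difference
    sign_test_p: float           # one-sided: one-cue > two-cue decoding
    r: float                     # brain-behavior correlation (stimulus window)
    r_p: float


def cueing_gain_experiment(n_subjects: int = 20, seed: int = 0, k: int = 5,
                           iterations: int = 2,
                           gain_subject_sd: float = 0.25) -> CueingGainResult:
    """One-cue vs two-cue contrast with the generator's default 2:1 gain ratio.

    Each subject's one-cue gain (and, coupled, the observer's one-cue template
    strength) is scaled by an individual factor, so the cohort yields both the
    group contrast (sign test on evoked-window decoding accuracy) and a
    brain-behavior correlation between the per-subject hit-rate difference and
    stimulus-window decoding difference.
    """
    cfg = RunConfig(n_subjects=n_subjects, master_seed=seed,
                    gain_subject_sd=gain_subject_sd, k_folds=k,
                    decode_iterations=iterations)
    acc_one, acc_two, hit_one, hit_two, stim_diff = [], [], [], [], []
    for s in range(n_subjects):
        gen, obs, _ = subject_params(cfg, s)
        rng = np.random.default_rng([seed, s, 31])
        schedule = build_eeg_schedule(rng)
        record = simulate_session(gen, schedule, rng)
        epochs = preprocess_session(record, schedule, locks=("target",))
        del record
        responses = simulate_observer(obs, schedule,
                                      np.random.default_rng([seed, s, 32]))
        retained = epochs["target"].trial_meta["trial_index"].to_numpy()
        behav = behavioral_summary(responses, retained).set_index("cue_condition")
        results = _decode_target_conditions(epochs["target"], k, iterations,
                                            np.random.default_rng([seed, s, 33]))
        t = results["one"].times
        acc_one.append(stats.windowed_mean(results["one"].accuracy, t, EVOKED_WINDOW))
        acc_two.append(stats.windowed_mean(results["two"].accuracy, t, EVOKED_WINDOW))
        hit_one.append(float(behav.loc["one", "hit_rate"]))
        hit_two.append(float(behav.loc["two", "hit_rate"]))
        stim_diff.append(
            stats.windowed_mean(results["one"].accuracy, t,
                                (0.0, behav.loc["one", "hit_rt_median"]))
            - stats.windowed_mean(results["two"].accuracy, t,
                                  (0.0, behav.loc["two", "hit_rt_median"])))
    acc_one, acc_two = np.array(acc_one), np.array(acc_two)
    hit_one, hit_two = np.array(hit_one), np.array(hit_two)
    stim_diff = np.array(stim_diff)
    n_pos = int((acc_one > acc_two).sum())
    sign_p = float(scipy.stats.binomtest(n_pos, n_subjects, 0.5,
                                         alternative="greater").pvalue)
    r, r_p = stats.brain_behavior_correlation(hit_one - hit_two, stim_diff)
    return CueingGainResult(acc_one, acc_two, hit_one, hit_two, stim_diff,
                            sign_p, r, r_p)


def cluster_test_fwer(n_sims: int = 200, n_subjects: int = 20, n_times: int = 100,
                      n_perm: int = 500, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Family-wise false-positive rate of the paired cluster test under the null."""
    rng = np.random.default_rng([seed, 41])
    false_positives = 0
    for _ in range(n_sims):
        a = rng.normal(size=(n_subjects, n_times))
        b = rng.normal(size=(n_subjects, n_times))
        res = stats.cluster_permutation_paired(a, b, n_perm=n_perm, alpha=alpha,
                                               rng=rng)
        if res.significant():
            false_positives += 1
    return false_positives / n_sims


@dataclass
class StaircaseRecoveryResult:
    mean_threshold: float
    sd: float
    oracle: float                # 70.7%-correct point of the observer
    per_replicate: np.ndarray


def staircase_recovery(n_replicates: int = 100, true_threshold: float = 0.44,
                       seed: int = 0) -> StaircaseRecoveryResult:
    """2-down-1-up recovery of a known observer threshold over seeded replicates."""
    observer = psychometric_observer(true_threshold)
    oracle = two_down_one_up_convergence_point(observer)
    means = []
    for rep in range(n_replicates):
        est = run_threshold_session(lambda c, coh: observer(coh),
                                    np.random.default_rng([seed, rep, 51]))
        means.append(np.mean([e.threshold for e in est.values()]))
    arr = np.array(means)
    return StaircaseRecoveryResult(float(arr.mean()), float(arr.std(ddof=1)),
                                   float(oracle), arr)
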