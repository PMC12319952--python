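"""End-to-end orchestration: simulate -> preprocess -> ERP/alpha -> decode -> stats.

A run is a pure function of its RunConfig: every random draw descends from the
master seed, so identical configs give byte-identical outputs. The desk
profile (12 subjects, 500 permutations, 2 decoding iterations) keeps a full
run tractable on one CPU; the full profile mirrors the experiment's scale
(28 subjects, 10,000 permutations, 10 iterations).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import decoding as dec
from . import erp_tfr, preprocessing as pre, stats
from .montage import CHANNELS_64, REFERENCE_PAIR
from .records import EpochSet
from .synthetic import GeneratorParams, ObserverParams, simulate_observer, simulate_session
from .task_design import build_eeg_schedule

logger = logging.getLogger(__name__)

PROFILES = {
    "desk": {"n_subjects": 12, "n_permutations": 500, "decode_iterations": 2},
    "full": {"n_subjects": 28, "n_permutations": 10_000, "decode_iterations": 10},
}

PREPARATORY_WINDOW = (0.5, 1.25)  # s post-cue, for the brain-behavior analysis


@dataclass
class RunConfig:
    """Serializable description of a complete pipeline run."""

    n_subjects: int = 12
    master_seed: int = 0
    profile: str = "desk"
    # generator
    evoked_gain: dict[str, float] = field(
        default_factory=lambda: {"no": 0.0, "one": 30.0, "two": 15.0, "three": 10.0})
    gain_subject_sd: float = 0.25   # per-subject scale on the one-cue gain
    couple_gain_behavior: bool = True
    noise_scale: float = 10.0
    cue_signal_gain: float = 12.0
    blink_rate: float = 0.0
    # observer
    observer_model: str = "weakened_template"
    template_strength: dict[str, float] = field(
        default_factory=lambda: {"one": 6.4, "two": 5.2, "three": 3.5, "no": 3.0})
    # preprocessing
    reject_threshold_uv: float = 200.0
    # analysis
    alpha_band: tuple[float, float] = (8.0, 14.0)
    run_tfr: bool = True
    tfr_srate: float = 250.0
    tfr_decim: int = 5
    k_folds: int = 5
    decode_iterations: int = 2
    smoothing_window: float = 0.040
    blocks_per_condition: int = 5
    n_permutations: int = 500
    alpha: float = 0.05
    montage: list[str] = field(default_factory=lambda: list(CHANNELS_64))
    output_dir: str = "attnpipe_out"

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "RunConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        kw = dict(PROFILES[profile])
        kw.update(overrides)
        return cls(profile=profile, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "alpha_band" in raw:
            raw["alpha_band"] = tuple(raw["alpha_band"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["alpha_band"] = list(self.alpha_band)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Range/completeness checks; an empty list means the config is valid."""
    issues = []
    if config.n_subjects < 2:
        issues.append("n_subjects: need at least 2 subjects for group statistics")
    if config.master_seed is None:
        issues.append("master_seed: a seed is required for reproducibility")
    lo, hi = config.alpha_band
    if not lo < hi:
        issues.append(f"alpha_band: ({lo}, {hi}) must be (low, high) with low < high")
    for ref in REFERENCE_PAIR:
        if ref not in config.montage:
            issues.append(f"montage: reference channel {ref} missing")
    if any(g < 0 for g in config.evoked_gain.values()):
        issues.append("evoked_gain: gains must be nonnegative")
    if config.k_folds < 2:
        issues.append("k_folds: need at least 2 folds")
    if config.decode_iterations < 1:
        issues.append("decode_iterations: need at least 1 iteration")
    if not 0 < config.alpha < 1:
        issues.append("alpha: significance level must lie in (0, 1)")
    if config.reject_threshold_uv <= 0:
        issues.append("reject_threshold_uv: threshold must be positive")
    return issues


# ---------------------------------------------------------------------------
# Per-subject simulation and analysis
# ---------------------------------------------------------------------------

def subject_params(config: RunConfig, subject: int) -> tuple[GeneratorParams, ObserverParams, float]:
    """Per-subject generator/observer parameters.

    Each subject's one-cue evoked gain is scaled by a random factor
    ``delta ~ N(1, gain_subject_sd)`` (clipped at 0.2); when
    ``couple_gain_behavior`` is set, the observer's one-cue template strength
    is scaled toward/away from the no-cue strength by the same factor, so a
    subject's neural cueing effect and behavioral cueing effect co-vary.
    """
    rng = np.random.default_rng([config.master_seed, subject, 11])
    delta = float(np.clip(rng.normal(1.0, config.gain_subject_sd), 0.2, None)) \
        if config.gain_subject_sd > 0 else 1.0
    gains = dict(config.evoked_gain)
    gains["one"] = gains["one"] * delta
    gen = GeneratorParams(
        noise_scale=config.noise_scale,
        evoked_gain=gains,
        cue_signal_gain=config.cue_signal_gain,
        blink_rate=config.blink_rate,
        subject_seed=int(np.random.default_rng([config.master_seed, subject]).integers(2**31)),
    )
    s = dict(config.template_strength)
    if config.couple_gain_behavior:
        s["one"] = s["no"] + (s["one"] - s["no"]) * delta
        s["one"] = max(s["one"], s["two"])  # preserve the ordering invariant
    obs = ObserverParams(model=config.observer_model, template_strength=s)
    return gen, obs, delta


def preprocess_session(record, schedule, threshold_uv: float = 200.0,
                       locks: tuple[str, ...] = ("cue", "target")) -> dict[str, EpochSet]:
    """Canonical order: rereference -> filter -> epoch+baseline -> reject."""
    rec = pre.rereference(record)
    rec = pre.filter_continuous(rec)
    out = {}
    for lock in locks:
        ep = pre.epoch_and_baseline(rec, schedule, lock=lock)
        out[lock] = pre.reject_artifacts(ep, threshold=threshold_uv)
    return out


def behavioral_summary(responses: pd.DataFrame, retained: np.ndarray) -> pd.DataFrame:
    """Per-condition hit/FA rates, median RTs and SDT measures.

    ``retained`` indexes the trials surviving artifact rejection, so behavior
    and EEG are computed on exactly the same trials.
    """
    resp = responses[responses["trial_index"].isin(retained)]
    rows = []
    for cond, g in resp.groupby("cue_condition"):
        tgt, noise = g[g["is_target"]], g[~g["is_target"]]
        n_hit = int((tgt["says_target"]).sum())
        n_fa = int((noise["says_target"]).sum())
        sdt = stats.sdt_measures(n_hit, len(tgt) - n_hit, n_fa, len(noise) - n_fa)
        hits = tgt[tgt["says_target"]]
        crs = noise[~noise["says_target"]]
        rows.append({
            "cue_condition": cond,
            "hit_rate": n_hit / max(len(tgt), 1),
            "fa_rate": n_fa / max(len(noise), 1),
            "hit_rt_median": float(hits["rt"].median()) if len(hits) else np.nan,
            "cr_rt_median": float(crs["rt"].median()) if len(crs) else np.nan,
            "dprime": sdt.dprime,
            "criterion": sdt.criterion,
        })
    return pd.DataFrame(rows)


def decode_subject(
    epochs_by_lock: dict[str, EpochSet],
    config: RunConfig,
    rng: np.random.Generator,
) -> dict[str, dict[str, dec.DecodingResult]]:
    """Cue-color (cue-locked) and target-color (target-locked) decoding.

    Target trials only. In the two-cue condition, cue-color decoding decodes
    each cue color separately and averages; target-color decoding always uses
    the target color as the label.
    """
    out: dict[str, dict[str, dec.DecodingResult]] = {}
    for lock, epochs in epochs_by_lock.items():
        prepared = dec.prepare_for_decoding(epochs)
        tgt = prepared.select_trials(prepared.trial_meta["is_target"].to_numpy().astype(bool))
        out[lock] = {}
        for cond in sorted(set(tgt.trial_meta["cue_condition"])):
            sub = tgt.select_trials((tgt.trial_meta["cue_condition"] == cond).to_numpy())
            if lock == "cue" and cond == "two":
                res = dec.decode_two_cue_colors(sub, k=config.k_folds,
                                                iterations=config.decode_iterations, rng=rng)
            else:
                res = dec.temporal_decode(sub, k=config.k_folds,
                                          iterations=config.decode_iterations, rng=rng)
            out[lock][cond] = dec.smooth_accuracy(res, config.smoothing_window)
    return out


# ---------------------------------------------------------------------------
# Group-level run
# ---------------------------------------------------------------------------

def _cluster_summary(result: stats.ClusterTestResult) -> list[dict[str, float]]:
    return [{"start_time": c.start_time, "end_time": c.end_time,
             "mass": c.mass, "p_value": c.p_value} for c in result.clusters]


def run_full_pipeline(config: RunConfig) -> dict[str, Any]:
    """Simulate and analyze a whole study; write TSV/JSON twins of every result."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    behav_rows, acc_rows = [], []
    erp_stack: dict[str, dict[str, list[np.ndarray]]] = {"cue": {}, "target": {}}
    alpha_stack: dict[str, list[np.ndarray]] = {}
    acc_stack: dict[str, dict[str, list[np.ndarray]]] = {"cue": {}, "target": {}}
    decode_times: dict[str, np.ndarray] = {}
    erp_times: dict[str, np.ndarray] = {}
    alpha_times = None
    rejection = {}
    behav_by_subject: list[pd.DataFrame] = []

    stage = "simulate"
    try:
        for s in range(config.n_subjects):
            t0 = time.time()
            gen, obs, _delta = subject_params(config, s)
            rng = np.random.default_rng([config.master_seed, s, 1])
            schedule = build_eeg_schedule(rng, n_blocks_per_cond=config.blocks_per_condition)
            stage = "simulate"
            record = simulate_session(gen, schedule, rng, channel_names=config.montage)
            responses = simulate_observer(obs, schedule, np.random.default_rng(
                [config.master_seed, s, 2]))
            timings.setdefault("simulate", 0.0)
            timings["simulate"] += time.time() - t0

            stage = "preprocess"
            t0 = time.time()
            epochs = preprocess_session(record, schedule, config.reject_threshold_uv)
            del record
            rejection[s] = {lock: float(ep.rejection_mask.mean())
                            for lock, ep in epochs.items()}
            timings.setdefault("preprocess", 0.0)
            timings["preprocess"] += time.time() - t0

            stage = "behavior"
            retained = epochs["target"].trial_meta["trial_index"].to_numpy()
            bs = behavioral_summary(responses, retained)
            bs.insert(0, "subject", s)
            behav_rows.append(bs)
            behav_by_subject.append(bs)

            stage = "erp_tfr"
            t0 = time.time()
            for lock, ep in epochs.items():
                erp = erp_tfr.compute_erp(ep)
                erp_times[lock] = erp.times
                for cond, wave in erp.amplitude.items():
                    erp_stack[lock].setdefault(cond, []).append(wave)
            if config.run_tfr:
                cue_tgt = epochs["cue"].select_trials(
                    epochs["cue"].trial_meta["is_target"].to_numpy().astype(bool))
                cue_tgt = pre.resample(cue_tgt, config.tfr_srate)
                tfr = erp_tfr.gabor_tfr(cue_tgt, decim=config.tfr_decim)
                tfr_db = erp_tfr.baseline_db(tfr)
                alpha = erp_tfr.band_power(tfr_db, config.alpha_band)
                alpha_times = tfr_db.times
                for cond, series in alpha.items():
                    alpha_stack.setdefault(cond, []).append(series)
            timings.setdefault("erp_tfr", 0.0)
            timings["erp_tfr"] += time.time() - t0

            stage = "decode"
            t0 = time.time()
            results = decode_subject(epochs, config,
                                     np.random.default_rng([config.master_seed, s, 3]))
            for lock, per_cond in results.items():
                for cond, res in per_cond.items():
                    decode_times[lock] = res.times
                    acc_stack[lock].setdefault(cond, []).append(res.accuracy)
                    for t, a in zip(res.times, res.accuracy):
                        acc_rows.append({"subject": s, "lock": lock, "condition": cond,
                                         "time": round(float(t), 4), "accuracy": float(a)})
            timings.setdefault("decode", 0.0)
            timings["decode"] += time.time() - t0
            logger.info("subject %d done", s)
    except Exception as e:  # partial outputs retained
        if behav_rows:
            pd.concat(behav_rows).to_csv(outdir / "behavior.tsv", sep="\t", index=False)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    stage = "stats"
    perm_rng = np.random.default_rng([config.master_seed, 10_001])
    report: dict[str, Any] = {"config": config.to_dict(), "rejection": rejection}

    behav = pd.concat(behav_rows, ignore_index=True)
    behav.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    conds = sorted(behav["cue_condition"].unique())
    report["behavior"] = {
        c: behav[behav["cue_condition"] == c].drop(columns=["subject", "cue_condition"])
        .mean().to_dict() for c in conds}
    if {"one", "two"} <= set(conds):
        wide = behav.pivot(index="subject", columns="cue_condition", values="hit_rate")
        ttest = stats.paired_t(wide["one"].to_numpy(), wide["two"].to_numpy())
        fa = behav.pivot(index="subject", columns="cue_condition", values="fa_rate")
        fa_test = stats.paired_t(fa["one"].to_numpy(), fa["two"].to_numpy())
        report["behavior_tests"] = {
            "hit_rate_one_vs_two": dataclasses.asdict(ttest),
            "fa_rate_one_vs_two": dataclasses.asdict(fa_test),
        }

    # ERP and alpha cluster tests (one-cue vs two-cue)
    report["erp"] = {}
    for lock in ("cue", "target"):
        rows = []
        for cond, stackl in erp_stack[lock].items():
            arr = np.stack(stackl)
            for i, t in enumerate(erp_times[lock]):
                rows.append({"condition": cond, "time": round(float(t), 4),
                             "amplitude": float(arr[:, i].mean())})
        pd.DataFrame(rows).to_csv(outdir / f"erp_{lock}.tsv", sep="\t", index=False)
        if {"one", "two"} <= set(erp_stack[lock]):
            res = stats.cluster_permutation_paired(
                np.stack(erp_stack[lock]["one"]), np.stack(erp_stack[lock]["two"]),
                times=erp_times[lock], n_perm=config.n_permutations,
                alpha=config.alpha, rng=perm_rng)
            report["erp"][lock] = {"one_vs_two_clusters": _cluster_summary(res)}
    if alpha_stack and {"one", "two"} <= set(alpha_stack):
        res = stats.cluster_permutation_paired(
            np.stack(alpha_stack["one"]), np.stack(alpha_stack["two"]),
            times=alpha_times, n_perm=config.n_permutations,
            alpha=config.alpha, rng=perm_rng)
        report["alpha"] = {"one_vs_two_clusters": _cluster_summary(res)}
        rows = [{"condition": c, "time": round(float(t), 4), "power_db": float(np.stack(v)[:, i].mean())}
                for c, v in alpha_stack.items() for i, t in enumerate(alpha_times)]
        pd.DataFrame(rows).to_csv(outdir / "alpha_power.tsv", sep="\t", index=False)

    pd.DataFrame(acc_rows).to_csv(outdir / "decoding_accuracy.tsv", sep="\t", index=False)
    report["decoding"] = {}
    for lock in ("cue", "target"):
        report["decoding"][lock] = {}
        for cond, stackl in acc_stack[lock].items():
            arr = np.stack(stackl)
            res = stats.cluster_permutation_vs_chance(
                arr, times=decode_times[lock], n_perm=config.n_permutations,
                alpha=config.alpha, rng=perm_rng)
            report["decoding"][lock][cond] = {
                "mean_peak_accuracy": float(arr.mean(axis=0).max()),
                "vs_chance_clusters": _cluster_summary(res)}
        if {"one", "two"} <= set(acc_stack[lock]):
            res = stats.cluster_permutation_paired(
                np.stack(acc_stack[lock]["one"]), np.stack(acc_stack[lock]["two"]),
                times=decode_times[lock], n_perm=config.n_permutations,
                alpha=config.alpha, rng=perm_rng)
            report["decoding"][lock]["one_vs_two_clusters"] = _cluster_summary(res)

    # brain-behavior correlation
    if {"one", "two"} <= set(acc_stack["target"]) and config.n_subjects >= 4:
        hit_diff, prep_diff, stim_diff = [], [], []
        for s in range(config.n_subjects):
            bs = behav_by_subject[s].set_index("cue_condition")
            hit_diff.append(bs.loc["one", "hit_rate"] - bs.loc["two", "hit_rate"])
            acc_one = acc_stack["target"]["one"][s]
            acc_two = acc_stack["target"]["two"][s]
            t_tgt = decode_times["target"]
            stim_diff.append(
                stats.windowed_mean(acc_one, t_tgt, (0.0, bs.loc["one", "hit_rt_median"]))
                - stats.windowed_mean(acc_two, t_tgt, (0.0, bs.loc["two", "hit_rt_median"])))
            c_one = acc_stack["cue"]["one"][s]
            c_two = acc_stack["cue"]["two"][s]
            t_cue = decode_times["cue"]
            prep_diff.append(stats.windowed_mean(c_one, t_cue, PREPARATORY_WINDOW)
                             - stats.windowed_mean(c_two, t_cue, PREPARATORY_WINDOW))
        r_stim, p_stim = stats.brain_behavior_correlation(hit_diff, stim_diff)
        r_prep, p_prep = stats.brain_behavior_correlation(hit_diff, prep_diff)
        report["brain_behavior"] = {
            "stimulus": {"r": r_stim, "p": p_stim},
            "preparatory": {"r": r_prep, "p": p_prep},
        }
        pd.DataFrame({"subject": range(config.n_subjects), "hit_rate_diff": hit_diff,
                      "stimulus_decoding_diff": stim_diff,
                      "preparatory_decoding_diff": prep_diff}
                     ).to_csv(outdir / "brain_behavior.tsv", sep="\t", index=False)

    timings["total"] = time.time() - t_start
    report["timings"] = {k: round(v, 2) for k, v in timings.items()}
    report["seeds"] = {"master": config.master_seed}
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    return report
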