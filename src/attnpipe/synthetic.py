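"""Synthetic EEG and behavioral-observer simulation.

The generator produces 64-channel continuous records with the statistical
structure the downstream analyses assume:

* 1/f background noise (configurable spectral exponent and scale);
* a posterior alpha oscillation (~10 Hz) with event-related suppression
  following every visual onset (cue display and dot field);
* a color-specific evoked spatial pattern added on target trials, time-locked
  to stimulus onset, whose amplitude scales with an attention gain ``g_k``
  that decreases with the number of cued colors and with the coherence signal
  above the noise floor (coherence - 0.2);
* a cue-color pattern during the cue display (split across cues when two
  cues are shown) and, optionally attenuated, through the preparatory period;
* optional blink-like frontal artifacts exceeding the rejection threshold.

The behavioral observer implements the two candidate accounts of the
attentional-template limit: a *weakened-template* observer whose sensitivity
multiplier s_k drops with the number of cued colors, and a *switching*
observer that attends one cued color at a time, chosen uniformly per trial.

Everything is a pure function of (parameters, schedule, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .montage import CHANNELS_64, FRONTAL, PALETTE, POSTERIOR_17, channel_indices
from .records import Record
from .task_design import CUE_DURATION, NOISE_COHERENCE, TrialSchedule


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic EEG generator (voltages in microvolts)."""

    srate: float = 500.0
    noise_exponent: float = 1.0       # 1/f^exponent background
    noise_scale: float = 10.0         # background standard deviation, uV
    alpha_freq: float = 10.0          # Hz
    alpha_amplitude: float = 5.0      # uV (posterior channels)
    alpha_suppression: float = 0.5    # fractional event-related suppression depth
    #: attention gain on the target-evoked pattern, per cue condition
    #: (uV per unit coherence above the 0.2 noise floor)
    evoked_gain: Mapping[str, float] = field(
        default_factory=lambda: {"no": 0.0, "one": 30.0, "two": 15.0, "three": 10.0})
    evoked_latency: float = 0.3       # s, bump peak after stimulus onset
    evoked_width: float = 0.1         # s, bump FWHM
    cue_signal_gain: float = 12.0     # uV, cue-color pattern during cue display
    preparatory_fraction: float = 0.15  # cue-pattern gain retained after cue offset
    blink_rate: float = 0.0           # blinks per minute
    subject_seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.evoked_gain.values()):
            raise ValueError("evoked gains must be nonnegative")
        if self.srate <= 2 * max(self.alpha_freq, 80.0):
            raise ValueError("srate must exceed twice the highest synthesized frequency")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the detection observer.

    ``template_strength`` maps cue condition to the sensitivity multiplier
    s_k applied to the coherence signal (evidence units per unit coherence
    above the noise floor); it must be non-increasing in the number of cues.
    """

    model: str = "weakened_template"  # or "switching"
    template_strength: Mapping[str, float] = field(
        default_factory=lambda: {"one": 6.4, "two": 5.2, "three": 3.5, "no": 3.0})
    internal_noise_sd: float = 1.0
    criterion: float = 0.25
    rt_base: float = 0.4              # s
    rt_slope: float = 0.4             # s, evidence-dependent component
    rt_noise_sd: float = 0.2          # lognormal sigma

    def __post_init__(self) -> None:
        s = self.template_strength
        if not (s["one"] >= s["two"] >= s["three"] >= s["no"] >= 0):
            raise ValueError("template strengths must satisfy s1 >= s2 >= s3 >= s_no >= 0")
        if self.model not in ("weakened_template", "switching"):
            raise ValueError(f"unknown observer model {self.model!r}")


# ---------------------------------------------------------------------------
# Spatial patterns
# ---------------------------------------------------------------------------

def color_topography(
    color: str,
    subject_seed: int,
    channel_names: list[str] | None = None,
    posterior_concentration: float = 0.08,
    max_abs_cos: float = 0.95,
) -> np.ndarray:
    """Fixed subject-specific scalp pattern for one color (unit norm).

    Weights are drawn once per (subject, color) from a Gaussian whose scale on
    non-posterior channels is ``posterior_concentration`` of the posterior
    scale, so the pattern is concentrated over visual cortex. Patterns are
    redrawn (deterministically) until the new pattern's |cosine| with every
    previously-indexed color pattern is below ``max_abs_cos``, guaranteeing
    the 7 patterns are mutually non-collinear.
    """
    channel_names = CHANNELS_64 if channel_names is None else channel_names
    if color not in PALETTE:
        raise ValueError(f"unknown color {color!r}")
    missing = set(POSTERIOR_17) - set(channel_names)
    if missing:
        raise KeyError(f"montage lacks posterior channels: {sorted(missing)}")
    post_idx = np.array(channel_indices(POSTERIOR_17, channel_names))

    earlier = [
        _draw_topography(c, subject_seed, channel_names, post_idx, posterior_concentration)
        for c in PALETTE[:PALETTE.index(color)]
    ]
    return _draw_topography(color, subject_seed, channel_names, post_idx,
                            posterior_concentration, earlier, max_abs_cos)


def _draw_topography(color, subject_seed, channel_names, post_idx,
                     concentration, earlier=(), max_abs_cos=0.95):
    for attempt in range(64):
        rng = np.random.default_rng([subject_seed, PALETTE.index(color), attempt, 7919])
        w = rng.normal(0.0, concentration, size=len(channel_names))
        w[post_idx] = rng.normal(0.0, 1.0, size=len(post_idx))
        w /= np.linalg.norm(w)
        if all(abs(float(w @ e)) < max_abs_cos for e in earlier):
            return w
    raise RuntimeError("could not draw a non-collinear topography")  # pragma: no cover


def all_topographies(subject_seed: int, channel_names: list[str] | None = None) -> dict[str, np.ndarray]:
    return {c: color_topography(c, subject_seed, channel_names) for c in PALETTE}


# ---------------------------------------------------------------------------
# Continuous-record simulation
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      srate: float, exponent: float, scale: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit-free scale uV."""
    nfft = scipy.fft.next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, nfft), dtype=np.float32)
    spec = scipy.fft.rfft(white, axis=1)
    freqs = scipy.fft.rfftfreq(nfft, 1.0 / srate)
    shaping = (freqs + 1.0) ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    spec *= shaping.astype(np.float32)
    out = scipy.fft.irfft(spec, n=nfft, axis=1)[:, :n_samples]
    out *= scale / max(out.std(), 1e-12)
    return out if out.dtype == np.float32 else out.astype(np.float32)


def _gaussian_bump(srate: float, peak: float, fwhm: float) -> tuple[np.ndarray, int]:
    """Unit-peak Gaussian; returns (waveform, sample offset of its first sample)."""
    sd = fwhm / 2.3548200450309493
    half = int(round(3.5 * sd * srate))
    t = np.arange(-half, half + 1) / srate
    offset = int(round(peak * srate)) - half
    return np.exp(-0.5 * (t / sd) ** 2), offset


def _add_pattern(data: np.ndarray, topo: np.ndarray, waveform: np.ndarray,
                 start: int) -> None:
    stop = start + len(waveform)
    lo, hi = max(start, 0), min(stop, data.shape[1])
    if hi <= lo:
        return
    data[:, lo:hi] += np.outer(topo, waveform[lo - start:hi - start])


def simulate_session(
    gen: GeneratorParams,
    schedule: TrialSchedule,
    rng: np.random.Generator,
    channel_names: list[str] | None = None,
) -> Record:
    """Continuous 64-channel record with cue/stim event markers for a schedule."""
    channel_names = CHANNELS_64 if channel_names is None else channel_names
    if set(POSTERIOR_17) - set(channel_names):
        raise KeyError("montage lacks the posterior channel cluster")
    srate = gen.srate
    last = schedule.trials[-1]
    duration = last.stim_onset + 5.0
    n = int(round(duration * srate))

    data = _one_over_f_noise(rng, len(channel_names), n, srate,
                             gen.noise_exponent, gen.noise_scale)

    # --- posterior alpha with event-related suppression -------------------
    onsets = []
    for t in schedule.trials:
        onsets.append(t.onset)        # cue display onset
        onsets.append(t.stim_onset)   # dot-field onset
    alpha_carrier = rng.standard_normal(n, dtype=np.float32)
    sos = scipy.signal.butter(2, [gen.alpha_freq - 1.5, gen.alpha_freq + 1.5],
                              btype="bandpass", fs=srate, output="sos")
    alpha_carrier = scipy.signal.sosfilt(sos, alpha_carrier).astype(np.float32)
    alpha_carrier *= gen.alpha_amplitude / max(alpha_carrier.std(), 1e-12)
    envelope = np.ones(n, dtype=np.float32)
    dip, dip_off = _gaussian_bump(srate, peak=0.45, fwhm=0.5)
    impulses = np.zeros(n, dtype=np.float32)
    for onset in onsets:
        i = int(round(onset * srate))
        if 0 <= i < n:
            impulses[i] = 1.0
    dip_resp = scipy.signal.fftconvolve(impulses, dip)[-dip_off: n - dip_off]
    envelope -= gen.alpha_suppression * np.clip(dip_resp, 0.0, 1.0)
    envelope = np.clip(envelope, 0.05, None)
    alpha_profile = np.full(len(channel_names), 0.15, dtype=np.float32)
    alpha_profile[channel_indices(POSTERIOR_17, channel_names)] = 1.0
    data += np.outer(alpha_profile, alpha_carrier * envelope)

    # --- cue-color and target-evoked patterns ------------------------------
    topos = {c: t.astype(np.float32)
             for c, t in all_topographies(gen.subject_seed, channel_names).items()}
    cue_bump, cue_off = _gaussian_bump(srate, peak=0.25, fwhm=0.25)
    ev_bump, ev_off = _gaussian_bump(srate, gen.evoked_latency, gen.evoked_width)
    cue_bump = cue_bump.astype(np.float32)
    ev_bump = ev_bump.astype(np.float32)
    events = []
    for idx, t in enumerate(schedule.trials):
        cue_sample = int(round(t.onset * srate))
        stim_sample = int(round(t.stim_onset * srate))
        events.append((cue_sample, t.onset, "cue", idx))
        events.append((stim_sample, t.stim_onset, "stim", idx))
        # cue display: each cued color's pattern, energy split across cues
        if t.cued_colors and gen.cue_signal_gain > 0:
            g = gen.cue_signal_gain / len(t.cued_colors)
            for color in t.cued_colors:
                _add_pattern(data, topos[color] * g, cue_bump, cue_sample + cue_off)
                if gen.preparatory_fraction > 0:
                    prep = np.full(max(stim_sample - cue_sample - int(CUE_DURATION * srate), 0),
                                   g * gen.preparatory_fraction, dtype=np.float32)
                    _add_pattern(data, topos[color], prep,
                                 cue_sample + int(CUE_DURATION * srate))
        # target-evoked pattern: gain x coherence above the noise floor
        if t.is_target:
            amp = gen.evoked_gain.get(t.cue_condition, 0.0) * (t.coherence - NOISE_COHERENCE)
            if amp > 0:
                _add_pattern(data, topos[t.target_color] * amp, ev_bump,
                             stim_sample + ev_off)

    # --- blink artifacts ---------------------------------------------------
    if gen.blink_rate > 0:
        n_blinks = rng.poisson(gen.blink_rate * duration / 60.0)
        blink_topo = np.zeros(len(channel_names))
        blink_topo[channel_indices([c for c in FRONTAL if c in channel_names],
                                   channel_names)] = 1.0
        blink_wave, _ = _gaussian_bump(srate, peak=0.0, fwhm=0.2)
        for _ in range(n_blinks):
            at = int(rng.uniform(0, n))
            _add_pattern(data, blink_topo * 300.0, blink_wave * rng.uniform(1.0, 1.5), at)

    events_df = pd.DataFrame(events, columns=["sample", "time", "kind", "trial_index"])
    return Record(data, srate, list(channel_names), events_df)


# ---------------------------------------------------------------------------
# Behavioral observer
# ---------------------------------------------------------------------------

def simulate_observer(
    obs: ObserverParams,
    schedule: TrialSchedule,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Yes/no responses and RTs for every trial of a schedule.

    Evidence on each trial is ``s_eff * (coherence - 0.2) + N(0, sd)`` and the
    observer responds "target" when evidence exceeds the criterion. The
    weakened-template observer uses ``s_eff = s_k`` for cue condition k; the
    switching observer attends one cued color (uniform per trial) and applies
    the one-cue strength only when the attended color is the cued color
    actually present in the display, falling back to the no-cue strength
    otherwise.
    """
    rows = []
    s = obs.template_strength
    for idx, t in enumerate(schedule.trials):
        if obs.model == "weakened_template" or t.cue_condition in ("no", "one"):
            s_eff = s[t.cue_condition] if t.cue_condition != "no" else s["no"]
            if obs.model != "weakened_template" and t.cue_condition == "one":
                s_eff = s["one"]
        else:  # switching, >= 2 cues
            attended = t.cued_colors[int(rng.integers(len(t.cued_colors)))]
            s_eff = s["one"] if attended == t.target_color else s["no"]
        evidence = s_eff * (t.coherence - NOISE_COHERENCE) + rng.normal(0.0, obs.internal_noise_sd)
        says_target = evidence > obs.criterion
        rt = (obs.rt_base + obs.rt_slope * np.exp(-abs(evidence - obs.criterion))) \
            * rng.lognormal(0.0, obs.rt_noise_sd)
        rows.append({
            "trial_index": idx,
            "cue_condition": t.cue_condition,
            "is_target": t.is_target,
            "says_target": bool(says_target),
            "correct": bool(says_target == t.is_target),
            "rt": float(rt),
        })
    return pd.DataFrame(rows)


def psychometric_observer(threshold: float, slope: float = 12.0):
    """Monotone P(correct | coherence) with a known 70.7%-correct point.

    A logistic from 0.5 to 1 whose sqrt(0.5) crossing sits exactly at
    ``threshold``; usable directly with run_threshold_session.
    """
    target_p = np.sqrt(0.5)
    # solve the logistic offset so p(threshold) = target_p
    # p(c) = 0.5 + 0.5 / (1 + exp(-slope * (c - c0)))
    inner = (target_p - 0.5) / 0.5
    c0 = threshold + np.log(1.0 / inner - 1.0) / slope

    def p_correct(color_or_coh, coherence=None):
        c = color_or_coh if coherence is None else coherence
        return 0.5 + 0.5 / (1.0 + np.exp(-slope * (c - c0)))

    return p_correct
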