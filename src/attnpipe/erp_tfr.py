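"""Univariate analyses: posterior-cluster ERPs and Gabor-wavelet spectral power.

ERPs are computed per condition as the mean over target trials, then over the
17-electrode posterior cluster, yielding one waveform per condition per
subject.

Spectral power uses a bank of 60 Gabor (Morlet) wavelets with log-spaced
center frequencies from 2 to 80 Hz, Gaussian spectral SD sigma_f = f/5
(about 5-cycle wavelets) and unit-energy normalization. Power is computed per
trial (total power: induced + evoked) and averaged across trials. Baseline
normalization uses a *common* baseline: the time-averaged baseline power is
averaged across all conditions per frequency, every condition is divided by
it, and the ratio is expressed in dB (10*log10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .montage import POSTERIOR_17
from .records import EpochSet

ALPHA_BAND = (8.0, 14.0)


@dataclass
class ERPResult:
    """Per-condition electrode-averaged waveforms for one subject."""

    amplitude: dict[str, np.ndarray]  # condition -> (n_times,) uV
    times: np.ndarray
    electrode_set: tuple[str, ...]


@dataclass(frozen=True)
class WaveletBank:
    """Log-spaced Gabor wavelet bank."""

    n_wavelets: int = 60
    fmin: float = 2.0
    fmax: float = 80.0
    sigma_ratio: float = 5.0  # sigma_f = f / sigma_ratio (~5-cycle wavelets)

    @property
    def freqs(self) -> np.ndarray:
        return np.geomspace(self.fmin, self.fmax, self.n_wavelets)


@dataclass
class TFRResult:
    """Per-condition (n_freqs, n_times) power for one subject, usually in dB."""

    power: dict[str, np.ndarray]
    freqs: np.ndarray
    times: np.ndarray
    units: str = "dB"
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": ALPHA_BAND})


def compute_erp(
    epochs: EpochSet,
    electrode_set: list[str] | None = None,
    by: str = "cue_condition",
) -> ERPResult:
    """Condition ERPs: mean over target trials, then over posterior electrodes."""
    electrode_set = POSTERIOR_17 if electrode_set is None else electrode_set
    sub = epochs.select_channels(electrode_set)  # raises listing missing names
    target_mask = sub.trial_meta["is_target"].to_numpy().astype(bool)
    sub = sub.select_trials(target_mask)
    amplitude = {}
    for cond, grp in sub.trial_meta.groupby(by):
        idx = grp.index.to_numpy()
        amplitude[str(cond)] = sub.data[idx].mean(axis=0).mean(axis=0)
    return ERPResult(amplitude, sub.times.copy(), tuple(electrode_set))


def _gabor_wavelet(freq: float, srate: float, sigma_ratio: float) -> np.ndarray:
    """Complex Gabor atom at ``freq`` Hz, unit energy."""
    sigma_f = freq / sigma_ratio
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(4.0 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    w = np.exp(2j * np.pi * freq * t) * np.exp(-t**2 / (2 * sigma_t**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def gabor_tfr(
    epochs: EpochSet,
    bank: WaveletBank | None = None,
    electrode_set: list[str] | None = None,
    decim: int = 1,
) -> TFRResult:
    """Raw total power: per-trial wavelet transform, squared, trial-averaged.

    Returns power (n_freqs, n_times // decim) averaged over trials and over
    ``electrode_set`` (default: the posterior cluster), per condition, in
    uV^2 ("raw" units). Frequencies above Nyquist raise a ValueError; epochs
    must be at least 3 of the longest wavelet lengths.
    """
    bank = WaveletBank() if bank is None else bank
    electrode_set = POSTERIOR_17 if electrode_set is None else electrode_set
    if bank.fmax >= epochs.srate / 2:
        raise ValueError("wavelet frequency above Nyquist")
    longest = 2 * int(np.ceil(4.0 * bank.sigma_ratio / (2 * np.pi * bank.fmin) * epochs.srate)) + 1
    if epochs.data.shape[2] < longest / 3:
        raise ValueError("epoch too short for the lowest-frequency wavelet")

    sub = epochs.select_channels(electrode_set)
    n = sub.data.shape[2]
    nfft = scipy.fft.next_fast_len(n + longest)
    n_times_out = len(epochs.times[::decim])

    conditions = sub.trial_meta["cue_condition"].to_numpy()
    uniq = sorted(set(conditions))
    sums = {c: np.zeros((bank.n_wavelets, n_times_out)) for c in uniq}
    counts = {c: int((conditions == c).sum()) for c in uniq}
    wavelets = [(_gabor_wavelet(f, epochs.srate, bank.sigma_ratio)) for f in bank.freqs]
    spectra = [scipy.fft.fft(w, n=nfft) for w in wavelets]

    chunk = 64  # trials per block, caps FFT memory
    for lo in range(0, sub.data.shape[0], chunk):
        block = slice(lo, lo + chunk)
        X = scipy.fft.fft(sub.data[block], n=nfft, axis=2)
        conds_block = conditions[block]
        for fi, (w, W) in enumerate(zip(wavelets, spectra)):
            half = (len(w) - 1) // 2
            conv = scipy.fft.ifft(X * W[None, None, :], axis=2)
            power = np.abs(conv[:, :, half:half + n:decim]) ** 2  # align to input
            mean_ch = power.mean(axis=1)  # (trials, times)
            for c in uniq:
                m = conds_block == c
                if m.any():
                    sums[c][fi] += mean_ch[m].sum(axis=0)
    out = {c: sums[c] / counts[c] for c in uniq}
    return TFRResult(out, bank.freqs, epochs.times[::decim].copy(), units="raw")


def baseline_db(
    tfr: TFRResult,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
) -> TFRResult:
    """Common-baseline dB normalization across conditions.

    The baseline power (time-averaged within ``baseline_window``) is averaged
    across all conditions per frequency; each condition's power is divided by
    this common baseline and converted to dB.
    """
    if tfr.units == "dB":
        raise ValueError("TFR already in dB")
    if len(tfr.power) < 2:
        raise ValueError("common baseline requires at least 2 conditions")
    mask = (tfr.times >= baseline_window[0] - 1e-9) & (tfr.times <= baseline_window[1] + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside TFR time range")
    base = np.mean([p[:, mask].mean(axis=1) for p in tfr.power.values()], axis=0)
    if np.any(base <= 0):
        raise FloatingPointError("zero or negative baseline power")
    power_db = {c: 10.0 * np.log10(p / base[:, None]) for c, p in tfr.power.items()}
    return TFRResult(power_db, tfr.freqs.copy(), tfr.times.copy(), units="dB",
                     bands=dict(tfr.bands))


def band_power(tfr: TFRResult, band: tuple[float, float] = ALPHA_BAND) -> dict[str, np.ndarray]:
    """Per-condition time course averaged over wavelets inside ``band`` (Hz)."""
    lo, hi = band
    if hi <= lo:
        raise ValueError(f"band {band} must be (low, high) with low < high")
    mask = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no wavelet centers inside band {band}")
    return {c: p[mask].mean(axis=0) for c, p in tfr.power.items()}
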