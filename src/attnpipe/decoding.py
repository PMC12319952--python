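"""Per-timepoint multiclass color decoding.

A linear discriminant classifier (uniform priors, pooled within-class
covariance with a minimal ridge for invertibility) is trained and tested
independently at every time point on the 17 posterior channels, using
stratified (class-balanced) k-fold cross-validation. The whole procedure is
repeated over independently re-partitioned iterations and averaged; the
resulting accuracy time series may be smoothed with a centered moving mean.
With 7 color classes, chance accuracy is 1/7.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage
import scipy.signal

from .montage import POSTERIOR_17
from .preprocessing import resample
from .records import EpochSet

CHANCE = 1.0 / 7.0
RIDGE = 1e-6


@dataclass
class DecodingResult:
    """Accuracy time series for one subject/condition."""

    accuracy: np.ndarray
    times: np.ndarray
    chance: float = CHANCE
    n_iterations: int = 10
    k_folds: int = 5
    smoothing_window: float | None = None  # seconds, None = unsmoothed

    def __post_init__(self) -> None:
        if len(self.accuracy) != len(self.times):
            raise ValueError("accuracy and times must have equal length")
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracy must lie in [0, 1]")


def prepare_for_decoding(
    epochs: EpochSet,
    electrode_set: list[str] | None = None,
    target_rate: float = 100.0,
    lowpass: float = 15.0,
    gaussian_fwhm: float = 0.020,
) -> EpochSet:
    """Posterior-channel selection, 100 Hz resampling, 15 Hz low-pass, smoothing.

    The Gaussian smoothing window is interpreted as FWHM (default 20 ms).
    """
    sub = epochs.select_channels(POSTERIOR_17 if electrode_set is None else electrode_set)
    sub = resample(sub, target_rate)
    sos = scipy.signal.butter(4, lowpass, btype="lowpass", fs=sub.srate, output="sos")
    sub.data = scipy.signal.sosfiltfilt(sos, sub.data, axis=2)
    sigma = gaussian_fwhm / 2.3548200450309493 * sub.srate
    sub.data = scipy.ndimage.gaussian_filter1d(sub.data, sigma, axis=2)
    return sub


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAClassifier:
    """Multiclass LDA with pooled within-class covariance and uniform priors."""

    classes: np.ndarray
    weights: np.ndarray      # (n_features, n_classes), Sigma^-1 mu_k
    bias: np.ndarray         # (n_classes,), -0.5 mu_k' Sigma^-1 mu_k

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def train_lda(features: np.ndarray, labels: np.ndarray, ridge: float = RIDGE) -> LDAClassifier:
    """Fit LDA on (n_trials, n_features) with a ridge of ``ridge * trace/p``.

    Requires at least 2 trials per class. With ``ridge = 0`` a singular pooled
    covariance raises a LinAlgError advising shrinkage.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError(f"class {classes[np.argmin(counts)]!r} has fewer than 2 trials")
    n, p = X.shape
    mu = np.stack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
    Xc = X - mu[y_idx]
    cov = Xc.T @ Xc / (n - len(classes))
    if ridge > 0:
        cov = cov + ridge * (np.trace(cov) / p) * np.eye(p)
    try:
        weights = np.linalg.solve(cov, mu.T)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; use a nonzero ridge (shrinkage)") from e
    bias = -0.5 * np.einsum("kp,pk->k", mu, weights)
    return LDAClassifier(classes, weights, bias)


# ---------------------------------------------------------------------------
# Cross-validated temporal decoding
# ---------------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced fold assignment: each class's trials split across k folds.

    Surplus trials (counts not divisible by k) are retained and spread one per
    fold. A class with fewer than k trials raises an error naming the class.
    """
    y = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} trials, fewer than k={k}")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def _decode_once(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
                 folds: list[np.ndarray], ridge: float) -> np.ndarray:
    """Accuracy (n_times,) for one fold partition; batched LDA across time."""
    n, p, T = X.shape
    acc = np.zeros(T)
    all_idx = np.arange(n)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y_idx[train_mask]
        Xte, yte = X[test_idx], y_idx[test_idx]
        # class means (K, p, T) and pooled covariance (T, p, p)
        mu = np.stack([Xtr[ytr == k].mean(axis=0) for k in range(n_classes)])
        Xc = Xtr - mu[ytr]
        cov = np.einsum("nct,ndt->tcd", Xc, Xc) / (len(ytr) - n_classes)
        tr = np.trace(cov, axis1=1, axis2=2) / p
        cov += (ridge * tr)[:, None, None] * np.eye(p)[None]
        mu_t = np.transpose(mu, (2, 1, 0))                # (T, p, K)
        A = np.linalg.solve(cov, mu_t)                    # (T, p, K)
        bias = -0.5 * np.einsum("tpk,tpk->tk", mu_t, A)
        scores = np.einsum("npt,tpk->ntk", Xte, A) + bias[None]
        pred = scores.argmax(axis=2)                      # (n_test, T)
        acc += (pred == yte[:, None]).mean(axis=0)
    return acc / len(folds)


def temporal_decode(
    epochs: EpochSet,
    labels: np.ndarray | None = None,
    k: int = 5,
    iterations: int = 10,
    rng: np.random.Generator | None = None,
    ridge: float = RIDGE,
) -> DecodingResult:
    """Per-timepoint k-fold cross-validated LDA accuracy, iteration-averaged.

    ``labels`` defaults to the trials' target colors. Folds are re-partitioned
    independently on each of the ``iterations`` repeats (same rng stream), and
    the accuracy series is the mean across iterations of the fold-mean
    held-out proportion correct.
    """
    rng = np.random.default_rng() if rng is None else rng
    if labels is None:
        labels = epochs.trial_meta["target_color"].to_numpy()
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    X = np.asarray(epochs.data, dtype=float)
    acc = np.zeros(X.shape[2])
    for _ in range(iterations):
        folds = stratified_folds(y, k, rng)
        acc += _decode_once(X, y_idx, len(classes), folds, ridge)
    return DecodingResult(acc / iterations, epochs.times.copy(),
                          chance=1.0 / len(classes), n_iterations=iterations, k_folds=k)


def decode_two_cue_colors(
    epochs: EpochSet,
    k: int = 5,
    iterations: int = 10,
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Two-cue cue-color decoding: decode each cue color separately, average.

    Pass 1 labels trials by the first cued color (the target cue), pass 2 by
    the second (the cued but non-target color); separate classifiers per pass.
    """
    rng = np.random.default_rng() if rng is None else rng
    cued = epochs.trial_meta["cued_colors"].astype(str).str.split(",")
    if (cued.str.len() < 2).any():
        raise ValueError("every trial needs an ordered pair of cued colors")
    first = cued.str[0].to_numpy()
    second = cued.str[1].to_numpy()
    r1 = temporal_decode(epochs, first, k=k, iterations=iterations, rng=rng)
    r2 = temporal_decode(epochs, second, k=k, iterations=iterations, rng=rng)
    return replace(r1, accuracy=(r1.accuracy + r2.accuracy) / 2.0)


def smooth_accuracy(result: DecodingResult, window: float = 0.040) -> DecodingResult:
    """Centered moving-mean smoothing; the window shrinks at the edges."""
    dt = float(np.mean(np.diff(result.times)))
    if window < dt * (1 - 1e-9):
        raise ValueError("smoothing window shorter than the sample period")
    w = int(round(window / dt))
    if w <= 1:
        return replace(result, smoothing_window=window)
    kernel = np.ones(w)
    num = np.convolve(result.accuracy, kernel, mode="same")
    den = np.convolve(np.ones_like(result.accuracy), kernel, mode="same")
    return replace(result, accuracy=num / den, smoothing_window=window)
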