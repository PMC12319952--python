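"""Inferential machinery.

* Cluster-based permutation tests on time series (paired and one-sample
  vs. chance): per-sample t statistics, cluster formation at a two-tailed
  p < alpha threshold, cluster mass = sum of t within a run (positive and
  negative runs separate), and a sign-flip null summarized by the maximal
  absolute cluster mass. For n <= 12 subjects the 2^n sign flips are
  enumerated exhaustively; otherwise a seeded Monte-Carlo sample is drawn and
  p-values use the (1 + exceedances) / (1 + permutations) correction.
* One-way repeated-measures ANOVA with partial eta squared.
* Paired t-tests with Cohen's d = t / sqrt(n).
* Signal-detection measures (d', criterion) with log-linear correction.
* Within-participant SEM (remove subject offsets, Morey k/(k-1) correction).
* Brain-behavior Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """A test statistic with its degrees of freedom, p-value and effect size."""

    statistic: float
    df: tuple[float, ...]
    p: float
    kind: str                     # "t" or "F"
    d: float | None = None        # Cohen's d (paired designs)
    eta_p_sq: float | None = None  # partial eta squared (ANOVA)


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's d recomputed from a t value: d = t / sqrt(n)."""
    return t / np.sqrt(n)


def eta_p_sq_from_f(f: float, df1: float, df2: float) -> float:
    """Partial eta squared recomputed from F: df1*F / (df1*F + df2)."""
    return df1 * f / (df1 * f + df2)


# ---------------------------------------------------------------------------
# Cluster-based permutation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    start_time: float
    end_time: float
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    tail: str
    observed_stat: np.ndarray
    times: np.ndarray
    method: str = "montecarlo"    # or "exhaustive"

    def significant(self, level: float | None = None) -> list[Cluster]:
        level = self.alpha if level is None else level
        return [c for c in self.clusters if c.p_value <= level]


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal runs of samples with t > threshold or t < -threshold.

    Returns (start, stop_exclusive, mass) with mass = sum of t in the run.
    """
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t > threshold
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            out.append((int(start), int(stop), float(t[start:stop].sum())))
    return sorted(out)


def _max_cluster_mass(t: np.ndarray, threshold: float) -> float:
    clusters = _find_clusters(t, threshold)
    return max((abs(m) for _, _, m in clusters), default=0.0)


def _signflip_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics (n_perm, T) for sign-flipped paired differences.

    Sign flips leave the per-subject squares unchanged, so only the mean term
    is recomputed per permutation.
    """
    n = diffs.shape[0]
    sumsq = (diffs**2).sum(axis=0)
    mean = signs @ diffs / n
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def cluster_permutation_paired(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times: np.ndarray | None = None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    exhaustive_max_n: int = 12,
) -> ClusterTestResult:
    """Two-tailed paired cluster permutation test on (n_subjects, n_times) arrays.

    The null is random per-subject sign flips of the difference; each
    permutation is summarized by its maximal absolute cluster mass. Samples
    with zero variance across subjects are excluded from cluster formation
    (their t is set to 0) with a warning.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.asarray(series_b, dtype=float)
    if b.ndim == 0 or (b.ndim == 1 and a.shape[1] == len(b) and a.shape[0] != len(b)):
        b = np.broadcast_to(b, a.shape)
    b = np.atleast_2d(b)
    if a.shape != b.shape:
        raise ValueError("series must share (n_subjects, n_times) shape")
    n, T = a.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    times = np.arange(T, dtype=float) if times is None else np.asarray(times)

    diffs = a - b
    var0 = diffs.var(axis=0, ddof=1)
    if np.any(var0 == 0):
        warnings.warn("zero-variance samples excluded from cluster formation")
    threshold = float(scipy.stats.t.ppf(1 - alpha / 2, n - 1))
    t_obs = _signflip_t(diffs, np.ones((1, n)))[0]
    observed = _find_clusters(t_obs, threshold)

    if n <= exhaustive_max_n:
        method = "exhaustive"
        m = 2**n
        signs = 1.0 - 2.0 * ((np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1)
    else:
        method = "montecarlo"
        rng = np.random.default_rng() if rng is None else rng
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _signflip_t(diffs, signs)
    null_max = np.array([_max_cluster_mass(row, threshold) for row in t_null])

    clusters = []
    for start, stop, mass in observed:
        exceed = int(np.sum(null_max >= abs(mass) - 1e-12))
        if method == "exhaustive":
            p = exceed / len(null_max)  # identity flip always exceeds: p > 0
        else:
            p = (1 + exceed) / (1 + len(null_max))
        clusters.append(Cluster(float(times[start]), float(times[stop - 1]),
                                mass, p))
    return ClusterTestResult(clusters, len(null_max), alpha, "two-tailed",
                             t_obs, times, method)


def cluster_permutation_vs_chance(
    accuracy: np.ndarray,
    chance: float = 1.0 / 7.0,
    times: np.ndarray | None = None,
    **kwargs,
) -> ClusterTestResult:
    """One-sample cluster test of accuracy series against a chance level."""
    acc = np.atleast_2d(np.asarray(accuracy, dtype=float))
    return cluster_permutation_paired(acc, np.full_like(acc, chance),
                                      times=times, **kwargs)


# ---------------------------------------------------------------------------
# ANOVA / t-tests
# ---------------------------------------------------------------------------

def rm_anova_1way(values: np.ndarray) -> EffectSize:
    """One-way repeated-measures ANOVA on a complete (n_subjects, k) table."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be (n_subjects, n_conditions)")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    f = 0.0 if ms_err == 0 and ms_cond == 0 else ms_cond / ms_err
    p = float(scipy.stats.f.sf(f, df1, df2))
    return EffectSize(float(f), (df1, df2), p, kind="F",
                      eta_p_sq=eta_p_sq_from_f(f, df1, df2))


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> EffectSize:
    """Paired t-test with Cohen's d = t / sqrt(n)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired 1-d samples with n >= 2")
    n = len(a)
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return EffectSize(0.0, (n - 1,), 1.0, kind="t", d=0.0)
        warnings.warn("zero-variance differences: t is infinite")
        t = np.inf * np.sign(d.mean())
        return EffectSize(float(t), (n - 1,), 0.0, kind="t", d=float(np.sign(d.mean()) * np.inf))
    res = scipy.stats.ttest_rel(a, b)
    t = float(res.statistic)
    return EffectSize(t, (n - 1,), float(res.pvalue), kind="t", d=cohens_d_from_t(t, n))


# ---------------------------------------------------------------------------
# Signal detection theory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDTResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float


def sdt_from_rates(hit_rate: float, fa_rate: float) -> SDTResult:
    """d' and criterion from (already finite) hit and false-alarm rates."""
    z = scipy.stats.norm.ppf
    zh, zf = z(hit_rate), z(fa_rate)
    return SDTResult(hit_rate, fa_rate, float(zh - zf), float(-0.5 * (zh + zf)))


def sdt_measures(n_hits: int, n_misses: int, n_fas: int, n_crs: int) -> SDTResult:
    """SDT measures from counts, with the log-linear extreme-rate correction.

    Adds 0.5 to every cell and 1 to each denominator before computing rates,
    so perfect or empty cells still yield finite d'.
    """
    counts = (n_hits, n_misses, n_fas, n_crs)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    if n_hits + n_misses == 0 or n_fas + n_crs == 0:
        raise ValueError("need at least one signal and one noise trial")
    h = (n_hits + 0.5) / (n_hits + n_misses + 1.0)
    fa = (n_fas + 0.5) / (n_fas + n_crs + 1.0)
    return sdt_from_rates(h, fa)


# ---------------------------------------------------------------------------
# Error bars and correlation
# ---------------------------------------------------------------------------

def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Per-condition SEM corrected for within-participant comparison.

    Cousineau normalization (subtract each subject's mean, add the grand mean)
    followed by the Morey sqrt(k/(k-1)) bias correction.
    """
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    if k < 2:
        warnings.warn("single condition: returning the plain SEM")
        return x.std(axis=0, ddof=1) / np.sqrt(n)
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(k / (k - 1))


def brain_behavior_correlation(
    behavioral_effect: np.ndarray,
    neural_effect: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation between per-subject behavioral and neural effects.

    Returns (r, two-tailed p with n-2 df). Requires n >= 4 and nonzero
    variance in both vectors.
    """
    x = np.asarray(behavioral_effect, dtype=float)
    y = np.asarray(neural_effect, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("effects must be matched 1-d vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def windowed_mean(series: np.ndarray, times: np.ndarray,
                  window: tuple[float, float]) -> float:
    """Mean of a time series within [window[0], window[1]] (inclusive)."""
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} outside time axis")
    return float(np.asarray(series)[mask].mean())
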