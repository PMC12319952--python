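"""Cluster permutation tests, ANOVA/t effect sizes, SDT, error bars, correlation."""

import itertools

import numpy as np
import pytest
import scipy.stats

from attnpipe import stats


# ---------------------------------------------------------------------------
# Effect-size recomputation
# ---------------------------------------------------------------------------

# (t, n, d) triplets as reported for the practice and EEG sessions
T_TABLE = [
    (3.48, 25, 0.70), (3.88, 25, 0.78), (0.52, 25, 0.10),
    (3.01, 25, 0.60), (2.75, 25, 0.55), (1.01, 25, 0.20),
    (3.38, 25, 0.68), (3.01, 25, 0.60), (1.49, 25, 0.30),
    (3.16, 25, 0.63), (1.25, 25, 0.25), (1.33, 25, 0.27),
    (1.37, 28, 0.26), (6.36, 28, 1.20), (4.06, 28, 0.77), (4.65, 28, 0.88),
]
F_TABLE = [
    (14.40, 3, 72, 0.38), (13.65, 3, 72, 0.36),
    (13.75, 3, 72, 0.36), (5.91, 3, 72, 0.20),
]


@pytest.mark.parametrize("t, n, d", T_TABLE)
def test_cohens_d_recomputes_from_t(t, n, d):
    assert round(stats.cohens_d_from_t(t, n), 2) == pytest.approx(d)


@pytest.mark.parametrize("f, df1, df2, eta", F_TABLE)
def test_eta_p_sq_recomputes_from_f(f, df1, df2, eta):
    assert round(stats.eta_p_sq_from_f(f, df1, df2), 2) == pytest.approx(eta)


# ---------------------------------------------------------------------------
# Cluster permutation: brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_cluster_p(a, b, alpha=0.05):
    """Independent enumeration oracle: all 2^n sign flips via scipy t-tests."""
    d = a - b
    n, T = d.shape
    thr = scipy.stats.t.ppf(1 - alpha / 2, n - 1)

    def t_series(x):
        return np.array([scipy.stats.ttest_1samp(x[:, i], 0).statistic for i in range(T)])

    def clusters(t):
        found = []
        for sign in (1, -1):
            run = None
            for i, v in enumerate(sign * t > thr):
                if v and run is None:
                    run = i
                elif not v and run is not None:
                    found.append((run, i, t[run:i].sum()))
                    run = None
            if run is not None:
                found.append((run, T, t[run:T].sum()))
        return sorted(found)

    obs = clusters(t_series(d))
    null_max = []
    for flips in itertools.product([1.0, -1.0], repeat=n):
        td = t_series(d * np.array(flips)[:, None])
        cl = clusters(td)
        null_max.append(max((abs(m) for *_, m in cl), default=0.0))
    null_max = np.array(null_max)
    return [(s, e, m, np.mean(null_max >= abs(m) - 1e-12)) for s, e, m in obs]


class TestClusterPermutation:
    def test_identical_series_give_no_clusters(self):
        a = np.random.default_rng(0).normal(size=(8, 40))
        res = stats.cluster_permutation_paired(a, a.copy())
        assert res.clusters == []

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(5, 30))
        b = rng.normal(size=(5, 30))
        a[:, 10:16] += 1.8  # plant an effect
        res = stats.cluster_permutation_paired(a, b)
        assert res.method == "exhaustive" and res.n_permutations == 32
        oracle = brute_force_cluster_p(a, b)
        assert len(res.clusters) == len(oracle) > 0
        for c, (s, e, m, p) in zip(res.clusters, oracle):
            assert c.mass == pytest.approx(m, rel=1e-9)
            assert c.p_value == pytest.approx(p, abs=1e-12)

    def test_montecarlo_seed_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(14, 50))
        a[:, 20:30] += 0.9
        b = rng.normal(size=(14, 50))
        r1 = stats.cluster_permutation_paired(a, b, n_perm=300,
                                              rng=np.random.default_rng(5))
        r2 = stats.cluster_permutation_paired(a, b, n_perm=300,
                                              rng=np.random.default_rng(5))
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
        perm = np.random.default_rng(0).permutation(14)
        r3 = stats.cluster_permutation_paired(a[perm], b[perm], n_perm=300,
                                              rng=np.random.default_rng(5))
        assert [c.mass for c in r3.clusters] == pytest.approx(
            [c.mass for c in r1.clusters])

    def test_vs_chance_detects_planted_window(self):
        rng = np.random.default_rng(3)
        acc = rng.normal(1 / 7, 0.02, size=(16, 80))
        acc[:, 30:45] += 0.08
        res = stats.cluster_permutation_vs_chance(acc, times=np.arange(80) * 0.01,
                                                  n_perm=500, rng=rng)
        sig = res.significant()
        assert len(sig) >= 1
        best = max(sig, key=lambda c: abs(c.mass))
        assert 0.30 - 0.02 <= best.start_time <= 0.45
        assert 0.30 <= best.end_time <= 0.45 + 0.02

    def test_constant_chance_input_warns_zero_variance(self):
        acc = np.full((8, 20), 1 / 7)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = stats.cluster_permutation_vs_chance(acc)
        assert res.clusters == []

    def test_needs_five_subjects(self):
        with pytest.raises(ValueError, match="5 subjects"):
            stats.cluster_permutation_paired(np.zeros((4, 10)), np.ones((4, 10)))


class TestAnovaAndT:
    def test_identical_conditions_give_zero_f(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 4))
        res = stats.rm_anova_1way(x)
        assert res.statistic == pytest.approx(0.0)

    def test_toy_table_matches_brute_force_ss_decomposition(self):
        x = np.array([[4.0, 6.0, 8.0], [3.0, 7.0, 9.0], [5.0, 6.0, 10.0]])
        res = stats.rm_anova_1way(x)
        # hand sum-of-squares decomposition
        grand = x.mean()
        ss_cond = 3 * ((x.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((x.mean(1) - grand) ** 2).sum()
        ss_err = ((x - grand) ** 2).sum() - ss_cond - ss_subj
        f_hand = (ss_cond / 2) / (ss_err / 4)
        assert res.statistic == pytest.approx(f_hand)
        assert res.df == (2, 4)
        assert res.eta_p_sq == pytest.approx(2 * f_hand / (2 * f_hand + 4))

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4)) + np.array([0.0, 0.3, 0.5, 0.1])
        res = stats.rm_anova_1way(x)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 4),
            "cond": np.tile(np.arange(4), 10),
            "y": x.ravel(),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          effsize="np2")
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)
        assert res.eta_p_sq == pytest.approx(float(ref["np2"][0]), rel=1e-6)

    def test_paired_t_hand_example(self):
        a = np.array([10.0, 12.0, 9.0, 11.0])
        b = np.array([8.0, 11.0, 9.0, 9.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / 2)
        res = stats.paired_t(a, b)
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == (3,)
        assert res.d == pytest.approx(t_hand / 2)

    def test_paired_t_degenerate(self):
        a = np.arange(5.0)
        assert stats.paired_t(a, a).statistic == 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = stats.paired_t(a + 1.0, a)
        assert np.isinf(res.statistic)


class TestSDT:
    def test_symmetric_rates_give_zero(self):
        res = stats.sdt_measures(50, 50, 50, 50)
        assert res.dprime == pytest.approx(0.0)
        assert res.criterion == pytest.approx(0.0)

    def test_unit_z_rates_give_dprime_two(self):
        res = stats.sdt_from_rates(0.8413447, 0.1586553)
        assert res.dprime == pytest.approx(2.0, abs=1e-4)
        assert res.criterion == pytest.approx(0.0, abs=1e-4)

    def test_perfect_performance_stays_finite(self):
        res = stats.sdt_measures(100, 0, 0, 100)
        assert np.isfinite(res.dprime) and res.dprime > 3

    def test_rejects_empty_margins(self):
        with pytest.raises(ValueError):
            stats.sdt_measures(0, 0, 3, 4)


class TestWithinSubjectSEM:
    def test_pure_offsets_vanish(self):
        profile = np.array([1.0, 2.0, 3.0])
        x = profile[None, :] + np.array([0.0, 5.0, -2.0, 10.0])[:, None]
        assert stats.within_subject_sem(x) == pytest.approx(np.zeros(3), abs=1e-12)

    def test_two_condition_hand_computation(self):
        x = np.array([[1.0, 3.0], [2.0, 2.0], [0.0, 4.0]])
        centered = x - x.mean(axis=1, keepdims=True) + x.mean()
        expected = centered.std(axis=0, ddof=1) / np.sqrt(3) * np.sqrt(2)
        assert stats.within_subject_sem(x) == pytest.approx(expected)

    def test_subject_offset_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 4))
        y = x.copy()
        y[2] += 7.5
        assert stats.within_subject_sem(y) == pytest.approx(stats.within_subject_sem(x))


class TestBrainBehavior:
    def test_perfect_correlation(self):
        x = np.arange(6.0)
        r, p = stats.brain_behavior_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.brain_behavior_correlation(np.ones(6), np.arange(6.0))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="4 subjects"):
            stats.brain_behavior_correlation(np.arange(3.0), np.arange(3.0))

    def test_windowed_mean(self):
        times = np.arange(10) * 0.1
        series = np.arange(10.0)
        assert stats.windowed_mean(series, times, (0.2, 0.4)) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            stats.windowed_mean(series, times, (5.0, 6.0))
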