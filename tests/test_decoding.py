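"""Per-timepoint LDA decoding with class-balanced cross-validation."""

import numpy as np
import pytest

from attnpipe.decoding import (CHANCE, DecodingResult, decode_two_cue_colors,
                               prepare_for_decoding, smooth_accuracy,
                               stratified_folds, temporal_decode, train_lda)
from attnpipe.montage import PALETTE
from attnpipe.synthetic import all_topographies

from conftest import make_epochs


def signal_epochs(n_per_class=10, amp=1.0, noise=0.5, n_samples=30,
                  signal_window=(10, 20), seed=0, srate=100.0):
    """17-channel epochs whose color is a posterior pattern inside a window."""
    from attnpipe.montage import POSTERIOR_17, channel_indices

    rng = np.random.default_rng(seed)
    idx = channel_indices(POSTERIOR_17)
    topos = {c: t[idx] for c, t in all_topographies(subject_seed=seed).items()}
    colors = np.repeat(PALETTE, n_per_class)
    rng.shuffle(colors)
    data = rng.normal(0, noise, size=(len(colors), 17, n_samples))
    lo, hi = signal_window
    for i, c in enumerate(colors):
        data[i, :, lo:hi] += amp * topos[c][:, None]
    return make_epochs(data=data, colors=colors, srate=srate, tmin=-0.1)


class TestTrainLDA:
    def test_separable_classes_fit_perfectly(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.1, (20, 2)),
                       np.random.default_rng(1).normal(5, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        clf = train_lda(X, y)
        assert (clf.predict(X) == y).all()

    def test_matches_closed_form_fisher_discriminant(self):
        """2-class boundary equals Sigma^-1 (mu1 - mu0) from hand linear algebra."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.multivariate_normal([0, 0], [[2, 0.5], [0.5, 1]], 50),
                       rng.multivariate_normal([1, 2], [[2, 0.5], [0.5, 1]], 50)])
        y = np.array([0] * 50 + [1] * 50)
        clf = train_lda(X, y, ridge=0.0)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
        S = Xc.T @ Xc / (100 - 2)
        w_hand = np.linalg.solve(S, mu1 - mu0)
        w_ours = clf.weights[:, 1] - clf.weights[:, 0]
        assert np.allclose(w_ours, w_hand)

    def test_matches_sklearn_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(5)
        X = rng.normal(size=(70, 6))
        y = rng.integers(0, 7, 70)
        while np.bincount(y, minlength=7).min() < 2:
            y = rng.integers(0, 7, 70)
        Xt = rng.normal(size=(30, 6))
        ours = train_lda(X, y, ridge=1e-12).predict(Xt)
        ref = LinearDiscriminantAnalysis(solver="lsqr", priors=np.full(7, 1 / 7)
                                         ).fit(X, y).predict(Xt)
        assert (ours == ref).mean() > 0.95

    def test_too_few_trials_per_class(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            train_lda(np.zeros((3, 2)), np.array([0, 0, 1]))

    def test_singular_covariance_advises_shrinkage(self):
        X = np.zeros((8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            train_lda(X, y, ridge=0.0)


class TestStratifiedFolds:
    def test_folds_partition_and_balance(self, rng):
        labels = np.repeat(PALETTE, 45)
        folds = stratified_folds(labels, 5, rng)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(315))
        for f in folds:
            counts = {c: (labels[f] == c).sum() for c in PALETTE}
            assert set(counts.values()) == {9}  # 45/5 per class per fold

    def test_surplus_trials_retained(self, rng):
        labels = np.array(["a"] * 11 + ["b"] * 10)
        folds = stratified_folds(labels, 5, rng)
        assert sum(len(f) for f in folds) == 21

    def test_small_class_named_in_error(self, rng):
        labels = np.array(["a"] * 10 + ["rare"] * 3)
        with pytest.raises(ValueError, match="rare"):
            stratified_folds(labels, 5, rng)


class TestTemporalDecode:
    def test_matches_brute_force_cv_on_fixture(self):
        """Batched path equals an explicit per-timepoint train_lda loop."""
        ep = signal_epochs(n_per_class=6, amp=0.8, n_samples=8)
        labels = ep.trial_meta["target_color"].to_numpy()
        res = temporal_decode(ep, k=3, iterations=1,
                              rng=np.random.default_rng(11))
        folds = stratified_folds(labels, 3, np.random.default_rng(11))
        acc = np.zeros(8)
        for test_idx in folds:
            train = np.setdiff1d(np.arange(len(labels)), test_idx)
            for t in range(8):
                clf = train_lda(ep.data[train, :, t], labels[train])
                pred = clf.predict(ep.data[test_idx, :, t])
                acc[t] += (pred == labels[test_idx]).mean()
        acc /= len(folds)
        assert np.allclose(res.accuracy, acc)

    def test_signal_confined_to_window(self):
        ep = signal_epochs(n_per_class=12, amp=1.2, noise=0.4,
                           signal_window=(12, 22), n_samples=40)
        res = temporal_decode(ep, k=5, iterations=2, rng=np.random.default_rng(0))
        assert res.accuracy[14:20].mean() > 0.5
        assert abs(res.accuracy[:8].mean() - CHANCE) < 0.08
        assert abs(res.accuracy[30:].mean() - CHANCE) < 0.08

    def test_shuffled_labels_decode_at_chance(self):
        ep = signal_epochs(n_per_class=12, amp=1.0, n_samples=20)
        rng = np.random.default_rng(1)
        labels = ep.trial_meta["target_color"].to_numpy().copy()
        rng.shuffle(labels)
        res = temporal_decode(ep, labels, k=5, iterations=3, rng=rng)
        assert abs(res.accuracy.mean() - CHANCE) < 0.05

    def test_deterministic_under_seed(self):
        ep = signal_epochs(n_per_class=8, amp=0.6, n_samples=10)
        r1 = temporal_decode(ep, k=4, iterations=2, rng=np.random.default_rng(9))
        r2 = temporal_decode(ep, k=4, iterations=2, rng=np.random.default_rng(9))
        assert np.array_equal(r1.accuracy, r2.accuracy)

    def test_accuracy_monotone_in_signal_gain(self):
        means = []
        for amp in (0.0, 0.6, 1.2):
            accs = []
            for seed in range(3):
                ep = signal_epochs(n_per_class=8, amp=amp, noise=0.5,
                                   n_samples=16, signal_window=(4, 12), seed=seed)
                res = temporal_decode(ep, k=4, iterations=1,
                                      rng=np.random.default_rng(seed))
                accs.append(res.accuracy[5:11].mean())
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(CHANCE, abs=0.06)


class TestTwoCueDecoding:
    def _two_cue_epochs(self, amp_first=1.0, amp_second=0.0, seed=0):
        from attnpipe.montage import POSTERIOR_17, channel_indices

        rng = np.random.default_rng(seed)
        idx = channel_indices(POSTERIOR_17)
        topos = {c: t[idx] for c, t in all_topographies(subject_seed=seed).items()}
        first = np.repeat(PALETTE, 8)
        second = np.array([PALETTE[(PALETTE.index(c) + 1 + rng.integers(5)) % 7]
                           for c in first])
        data = rng.normal(0, 0.5, size=(len(first), 17, 12))
        for i in range(len(first)):
            data[i] += amp_first * topos[first[i]][:, None]
            data[i] += amp_second * topos[second[i]][:, None]
        ep = make_epochs(data=data, colors=first, srate=100.0)
        ep.trial_meta["cued_colors"] = [f"{a},{b}" for a, b in zip(first, second)]
        ep.trial_meta["cue_condition"] = "two"
        return ep

    def test_identical_passes_average_to_either(self):
        ep = self._two_cue_epochs(amp_first=0.8)
        ep.trial_meta["cued_colors"] = [f"{c},{c}" for c
                                        in ep.trial_meta["target_color"]]
        both = decode_two_cue_colors(ep, k=4, iterations=1,
                                     rng=np.random.default_rng(2))
        # the two passes share labels; a single pass with a fresh rng stream
        # drawing the same fold sequence gives the same accuracies
        rng = np.random.default_rng(2)
        single1 = temporal_decode(ep, k=4, iterations=1, rng=rng)
        single2 = temporal_decode(ep, k=4, iterations=1, rng=rng)
        assert np.allclose(both.accuracy, (single1.accuracy + single2.accuracy) / 2)

    def test_single_informative_cue_yields_midpoint(self):
        ep = self._two_cue_epochs(amp_first=1.5, amp_second=0.0, seed=4)
        res = decode_two_cue_colors(ep, k=4, iterations=2,
                                    rng=np.random.default_rng(0))
        # first pass decodes well, second at chance -> midpoint
        assert 0.3 < res.accuracy.mean() < 0.75

    def test_missing_second_cue_rejected(self):
        ep = self._two_cue_epochs()
        ep.trial_meta.loc[3, "cued_colors"] = "red"
        with pytest.raises(ValueError, match="pair"):
            decode_two_cue_colors(ep, rng=np.random.default_rng(0))


class TestPrepareAndSmooth:
    def test_output_rate_is_100hz(self, small_record, one_block_schedule):
        from attnpipe.preprocessing import epoch_and_baseline
        ep = epoch_and_baseline(small_record, one_block_schedule, lock="target")
        out = prepare_for_decoding(ep)
        assert out.srate == 100.0
        assert len(out.channel_names) == 17

    def test_30hz_attenuated(self):
        srate = 500.0
        t = np.arange(1500) / srate
        data = np.tile(np.sin(2 * np.pi * 30.0 * t), (3, 64, 1))
        ep = make_epochs(data=data, srate=srate, tmin=0.0)
        out = prepare_for_decoding(ep)
        mid = slice(40, -40)
        atten = 20 * np.log10(out.data[0, 0, mid].std() / data[0, 0, mid].std())
        assert atten <= -15

    def test_dc_passes_through(self):
        data = np.full((2, 64, 1000), 4.0)
        ep = make_epochs(data=data, srate=500.0, tmin=0.0)
        out = prepare_for_decoding(ep)
        assert np.allclose(out.data[:, :, 20:-20], 4.0, atol=0.05)

    def test_constant_series_unchanged_by_smoothing(self):
        res = DecodingResult(np.full(50, 0.3), np.arange(50) * 0.01)
        sm = smooth_accuracy(res, window=0.04)
        assert np.allclose(sm.accuracy, 0.3)

    def test_impulse_mass_preserved(self):
        acc = np.zeros(51)
        acc[25] = 1.0
        res = DecodingResult(acc, np.arange(51) * 0.01)
        sm = smooth_accuracy(res, window=0.04)
        spread = np.flatnonzero(sm.accuracy > 1e-12)
        assert 4 <= len(spread) <= 5
        assert sm.accuracy.sum() * 1 == pytest.approx(1.0)  # mass conserved

    def test_one_sample_window_is_identity(self):
        res = DecodingResult(np.random.default_rng(0).uniform(0, 1, 20),
                             np.arange(20) * 0.01)
        sm = smooth_accuracy(res, window=0.01)
        assert np.allclose(sm.accuracy, res.accuracy)

    def test_subsample_window_rejected(self):
        res = DecodingResult(np.zeros(10), np.arange(10) * 0.01)
        with pytest.raises(ValueError, match="window"):
            smooth_accuracy(res, window=0.001)
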