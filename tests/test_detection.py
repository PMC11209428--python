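"""Surrogate channel, features, and leave-one-out classification."""

import numpy as np
import pytest

from mrcpkit.data import ContinuousRecording, EpochSet, EventSeries, EEG_CHANNELS
from mrcpkit.detection import (
    FEATURE_NAMES,
    SURROGATE_NEIGHBORS,
    ClassifierSpec,
    FeatureMatrix,
    build_template,
    extract_detection_epochs,
    fold_template,
    loocv_classify,
    preprocess_detection,
    sample_idle_epochs,
    session_detection,
    spectral_features,
    surrogate_channel,
    temporal_features,
    template_feature,
)

FS = 500.0


def recording(data_by_channel):
    n = len(next(iter(data_by_channel.values())))
    data = np.zeros((11, n))
    for i, ch in enumerate(EEG_CHANNELS):
        if ch in data_by_channel:
            data[i] = data_by_channel[ch]
    return ContinuousRecording(data, FS, EEG_CHANNELS)


class TestSurrogate:
    def test_constant_field_cancels(self):
        rec = recording({ch: np.ones(100) for ch in EEG_CHANNELS})
        assert np.allclose(surrogate_channel(rec), 0.0)

    def test_center_minus_neighbor_mean(self):
        data = {ch: np.full(10, 2.0) for ch in SURROGATE_NEIGHBORS}
        data["Cz"] = np.full(10, 10.0)
        assert np.allclose(surrogate_channel(recording(data)), 8.0)

    def test_matches_direct_formula_on_random_input(self, rng):
        data = {ch: rng.normal(0, 5, 256) for ch in ("Cz",) + SURROGATE_NEIGHBORS}
        got = surrogate_channel(recording(data))
        brute = data["Cz"] - sum(data[ch] for ch in SURROGATE_NEIGHBORS) / 8.0
        assert np.array_equal(got, brute)

    def test_unused_channels_do_not_enter(self, rng):
        data = {ch: rng.normal(0, 5, 64) for ch in ("Cz",) + SURROGATE_NEIGHBORS}
        a = surrogate_channel(recording(data))
        data2 = dict(data, FP1=rng.normal(0, 50, 64), FCz=rng.normal(0, 50, 64))
        b = surrogate_channel(recording(data2))
        assert np.array_equal(a, b)

    def test_missing_channel_rejected(self, rng):
        rec = ContinuousRecording(rng.normal(0, 1, (3, 64)), FS, ("Cz", "F3", "Fz"))
        with pytest.raises(KeyError):
            surrogate_channel(rec)


class TestPreprocess:
    def test_constant_recording_gives_zero_surrogate(self):
        rec = recording({ch: np.full(6000, 7.0) for ch in EEG_CHANNELS})
        out = preprocess_detection(rec)
        assert out.channel_labels == ("surrogate",)
        assert np.max(np.abs(out.data[0][1000:-1000])) < 1e-6

    def test_out_of_band_oscillation_attenuated(self):
        from mrcpkit.filters import bandpass_magnitude

        t = np.arange(int(60 * FS)) / FS
        rec = recording({"Cz": np.sin(2 * np.pi * 40.0 * t)})
        out = preprocess_detection(rec)
        expected = bandpass_magnitude(40.0, 0.1, 30.0, FS)[0]
        mid = slice(int(10 * FS), int(50 * FS))
        got = np.max(np.abs(out.data[0][mid]))
        assert got == pytest.approx(expected, rel=0.05)


class TestEpochs:
    def test_two_second_epochs(self, small_session):
        sur = preprocess_detection(small_session.eeg)
        ep = extract_detection_epochs(sur, small_session.truth)
        assert ep.n_epochs <= len(small_session.truth)
        assert ep.epochs.shape[2] == 1000
        assert ep.t[0] == -2.0 and ep.t[-1] == pytest.approx(-1 / FS)

    def test_spiked_epoch_rejected(self, small_session):
        sur = preprocess_detection(small_session.eeg)
        x = sur.data[0].copy()
        i = int(small_session.truth.onset_times[3] * FS) - 500
        x[i] = 300.0
        spiked = ContinuousRecording(x[None, :], FS, ("surrogate",))
        ep = extract_detection_epochs(spiked, small_session.truth)
        assert not ep.kept_mask[3]
        assert ep.kept_mask.sum() == ep.n_epochs - 1


class TestIdleSampling:
    def _idle(self, rng, dur=120.0):
        return ContinuousRecording(
            rng.normal(0, 10, (1, int(dur * FS))), FS, ("surrogate",)
        )

    def test_count_and_start_range(self, rng):
        idle = self._idle(rng)
        ep = sample_idle_epochs(idle, 97, seed=3)
        assert ep.n_epochs == 97
        assert ep.epochs.shape[2] == 1000
        assert np.all(ep.labels == "idle")

    def test_seed_determinism(self, rng):
        idle = self._idle(rng)
        a = sample_idle_epochs(idle, 20, seed=5)
        b = sample_idle_epochs(idle, 20, seed=5)
        assert np.array_equal(a.epochs, b.epochs)

    def test_artifact_epochs_redrawn(self, rng):
        x = rng.normal(0, 10, int(120 * FS))
        x[30000:40000] = 200.0  # 20 s of artifact
        idle = ContinuousRecording(x[None, :], FS, ("surrogate",))
        ep = sample_idle_epochs(idle, 50, seed=1)
        assert np.max(np.abs(ep.epochs)) <= 125.0

    def test_unsatisfiable_request_errors(self, rng):
        x = np.full(int(10 * FS), 200.0)
        idle = ContinuousRecording(x[None, :], FS, ("surrogate",))
        with pytest.raises(ValueError, match="clean idle epochs"):
            sample_idle_epochs(idle, 5, seed=1)


class TestTemporalFeatures:
    def test_constant_epoch(self):
        f = temporal_features(np.full(1000, -3.0), FS)
        assert np.allclose(f, [-3, -3, -3, -3, 0])

    def test_linear_ramp_discrete_oracle(self):
        """Ramp 0 µV at -2 s to -8 µV at 0 s: quarter means at the sample
        midpoints, half-difference exactly 4 µV."""
        t = np.arange(-1000, 0) / FS
        f = temporal_features(-4.0 * (t + 2.0), FS)
        assert f == pytest.approx([-0.996, -2.996, -4.996, -6.996, 4.0])

    def test_matches_brute_force_window_means(self, rng):
        x = rng.normal(0, 5, 1000)
        f = temporal_features(x, FS)
        quarters = [x[i * 250 : (i + 1) * 250].mean() for i in range(4)]
        assert np.allclose(f[:4], quarters)
        assert f[4] == pytest.approx(x[:500].mean() - x[500:].mean())

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="2-s epoch"):
            temporal_features(np.zeros(999), FS)


class TestSpectralFeatures:
    def test_count_is_23(self, rng):
        assert len(spectral_features(rng.normal(0, 1, 1000), FS)) == 23

    def test_sinusoid_peaks_at_its_bin(self):
        t = np.arange(1000) / FS
        f = spectral_features(np.sin(2 * np.pi * 10.0 * t), FS)
        assert np.argmax(f) == 2  # bins start at 8 Hz

    def test_matches_manual_welch(self, rng):
        """Independent re-computation: three Hamming-windowed 1-s segments
        at 50% overlap, averaged periodograms, density scaling."""
        x = rng.normal(0, 2, 1000)
        win = np.hamming(501)[:500]  # periodic (DFT-even) Hamming window
        psds = []
        for start in (0, 250, 500):
            seg = x[start : start + 500]
            seg = (seg - seg.mean()) * win
            spec = np.abs(np.fft.rfft(seg)) ** 2
            scale = 1.0 / (FS * (win ** 2).sum())
            p = spec * scale
            p[1:-1] *= 2
            psds.append(p)
        manual = np.mean(psds, axis=0)[8:31]
        assert np.allclose(spectral_features(x, FS), manual, rtol=1e-10)

    def test_non_integer_fs_rejected(self):
        with pytest.raises(ValueError, match="integer sampling rate"):
            spectral_features(np.zeros(1001), 500.5)


class TestTemplateFeature:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(0, 3, 1000)
        assert template_feature(x, x) == pytest.approx(1.0)
        assert template_feature(-x, x) == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self, rng):
        x, tpl = rng.normal(0, 2, 1000), rng.normal(0, 2, 1000)
        got = template_feature(x, tpl)
        brute = np.sum(x * tpl) / np.sqrt(np.sum(x * x) * np.sum(tpl * tpl))
        assert got == pytest.approx(brute)
        assert -1 <= got <= 1

    def test_unnormalized_switch(self, rng):
        x, tpl = rng.normal(0, 2, 100), rng.normal(0, 2, 100)
        assert template_feature(x, tpl, normalize=False) == pytest.approx(float(x @ tpl))

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="zero-energy"):
            template_feature(np.zeros(10), np.ones(10))

    def test_template_is_training_mean_and_excludes_held_out(self, rng):
        epochs = rng.normal(0, 1, (10, 1000))
        labels = np.array(["mrcp"] * 5 + ["idle"] * 5)
        fm = FeatureMatrix(
            static=np.zeros((10, 28)), epochs=epochs, labels=labels, fs=FS
        )
        tpl = fold_template(fm, 2)
        assert np.allclose(tpl, epochs[[0, 1, 3, 4]].mean(axis=0))
        # leakage guard: perturbing only the held-out epoch leaves the
        # fold's template unchanged
        fm.epochs[2] += 1e6
        assert np.array_equal(fold_template(fm, 2), tpl)

    def test_template_recovery_from_noisy_copies(self, rng):
        base = -8 * np.hanning(1000)
        epochs = base + rng.normal(0, 2, (100, 1000))
        tpl = build_template(epochs)
        se = 2 / np.sqrt(100)
        assert np.max(np.abs(tpl - base)) < 5 * se

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="zero training epochs"):
            build_template(np.empty((0, 1000)))


def make_feature_matrix(rng, n_per_class=20, separation=0.0):
    """Synthetic FeatureMatrix with controllable class separation."""
    n = 2 * n_per_class
    epochs = rng.normal(0, 1, (n, 1000))
    epochs[:n_per_class] -= separation * np.hanning(1000)
    labels = np.array(["mrcp"] * n_per_class + ["idle"] * n_per_class)
    static = rng.normal(0, 1, (n, 28))
    static[:n_per_class, :5] += separation
    return FeatureMatrix(static=static, epochs=epochs, labels=labels, fs=FS)


class TestLoocv:
    @pytest.mark.parametrize("kind", ["random_forest", "lda", "knn"])
    def test_separable_clouds_classified_perfectly(self, rng, kind):
        fm = make_feature_matrix(rng, n_per_class=15, separation=10.0)
        res = loocv_classify(fm, ClassifierSpec(kind=kind, seed=0))
        assert res.accuracy == 100.0
        assert res.n_folds == 30

    def test_feature_dimensionality_is_29(self, rng):
        fm = make_feature_matrix(rng)
        X = fm.with_template(fold_template(fm, 0))
        assert X.shape[1] == 29 == len(FEATURE_NAMES)

    def test_deterministic_repetition(self, rng):
        fm = make_feature_matrix(rng, n_per_class=10, separation=1.0)
        a = loocv_classify(fm, ClassifierSpec(kind="random_forest", trees=32, seed=9))
        b = loocv_classify(fm, ClassifierSpec(kind="random_forest", trees=32, seed=9))
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.predictions, b.predictions)

    def test_permuted_labels_center_on_chance(self, rng):
        """Label permutation breaks the class structure: mean LOOCV accuracy
        over permutations sits within 2 pp of 50%."""
        fm = make_feature_matrix(rng, n_per_class=15, separation=3.0)
        accs = []
        for _ in range(40):
            perm = rng.permutation(fm.n_epochs)
            shuffled = FeatureMatrix(
                static=fm.static, epochs=fm.epochs, labels=fm.labels[perm], fs=FS
            )
            accs.append(loocv_classify(shuffled, ClassifierSpec(kind="lda")).accuracy)
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_imbalanced_classes_rejected(self, rng):
        fm = make_feature_matrix(rng, n_per_class=5)
        fm.labels[0] = "idle"
        with pytest.raises(ValueError, match="balanced"):
            loocv_classify(fm, ClassifierSpec(kind="lda"))


class TestEndToEnd:
    def test_accuracy_monotone_in_snr(self):
        """Classification accuracy does not degrade as background noise
        decreases (checked at three noise levels, one binomial SE slack)."""
        from mrcpkit.synth import SessionConfig, generate_session

        accs = []
        for noise in (10.0, 5.0, 2.5):
            cfg = SessionConfig(seed=42, n_movements=30, noise_sd=noise)
            sess = generate_session(cfg)
            r = session_detection(sess.eeg, sess.idle, sess.truth,
                                  [ClassifierSpec(kind="lda")], idle_seed=2)[0]
            accs.append((r.accuracy, r.n_folds))
        for (lo, n_lo), (hi, n_hi) in zip(accs, accs[1:]):
            se = 100 * np.sqrt(0.25 / min(n_lo, n_hi))
            assert hi >= lo - se

    def test_accuracy_in_study_regime(self, default_session):
        """A default-condition session lands near the ~80% single-trial
        accuracy regime for the forest and the linear classifier."""
        sess = default_session
        specs = [ClassifierSpec(kind=k, seed=1) for k in ("random_forest", "lda")]
        results = session_detection(sess.eeg, sess.idle, sess.truth, specs, idle_seed=1)
        for r in results:
            assert r.n_folds >= 190  # ~100 epochs per class after rejection
            assert 70.0 <= r.accuracy <= 90.0
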