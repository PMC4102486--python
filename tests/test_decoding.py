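"""Sliding-window space-time SVR decoding."""

import numpy as np
import pytest

import nirsvig as nv


class TestWindows:
    def test_printed_sample_endpoints(self):
        spec = nv.WindowSpec()
        assert spec.start_sample == -31
        assert spec.end_sample == 92

    def test_default_window_count(self):
        # floor((124 - 7) / 3) + 1 = 40 windows over [-31, 92]
        assert len(nv.enumerate_windows(nv.WindowSpec())) == 40

    def test_starts_step_and_fit(self):
        starts = nv.enumerate_windows(nv.WindowSpec())
        assert starts[0] == -31
        assert set(np.diff(starts)) == {3}
        assert starts[-1] + 7 - 1 <= 92

    def test_range_shorter_than_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            nv.enumerate_windows(nv.WindowSpec(start_time=0, end_time=0.5,
                                               width=7))


class TestFeatures:
    def test_feature_dimensions(self, small_session):
        _, data, _, norm = small_session
        hbo, hbr = norm[1]
        trials = data.trials_rec[data.trials_rec.run_id == 1]
        X, y, _ = nv.extract_features(hbo, hbr, trials, 0, 7)
        assert X.shape[1] == 88 * 7  # 616: both chromophores x 44 ch x width
        assert len(y) == len(X)

    def test_window_mean_reduction(self, small_session):
        _, data, _, norm = small_session
        hbo, hbr = norm[1]
        trials = data.trials_rec[data.trials_rec.run_id == 1]
        X, _, _ = nv.extract_features(hbo, hbr, trials, 0, 7, reduce="mean")
        assert X.shape[1] == 88

    def test_identical_signals_identical_rows(self):
        data = np.zeros((2, 200))
        data[:, 50:60] = 1.0
        data[:, 150:160] = 1.0
        rec = nv.Recording(data, 6.25, 1, "HbO")
        trials = _trials_at([8.0, 24.0])
        X, _, _ = nv.extract_features(rec, rec, trials, 0, 7)
        np.testing.assert_array_equal(X[0], X[1])

    def test_boundary_trials_dropped(self):
        rec = nv.Recording(np.zeros((2, 100)), 6.25, 1, "HbO")
        trials = _trials_at([1.0, 8.0])
        X, _, kept = nv.extract_features(rec, rec, trials, -31, 7)
        assert len(X) == 1 and kept.tolist() == [1]

    def test_all_trials_dropped_is_error(self):
        rec = nv.Recording(np.zeros((2, 100)), 6.25, 1, "HbO")
        with pytest.raises(ValueError, match="no trials"):
            nv.extract_features(rec, rec, _trials_at([1.0]), -31, 7)


def _trials_at(onsets, rtc=None):
    import pandas as pd
    n = len(onsets)
    rtc = np.zeros(n) if rtc is None else np.asarray(rtc)
    return pd.DataFrame({
        "trial_index": np.arange(n), "run_id": 1, "onset": onsets,
        "duration": 0.2, "condition": "congruent", "attention": "global",
        "correct": True, "rt": 550.0 + rtc, "rt_corrected": rtc,
        "vigilance": rtc})


def _linear_problem(rng, n_runs=3, n_trials=30, n_features=10, slope=5.0):
    feats, targs = {}, {}
    for r in range(1, n_runs + 1):
        X = np.zeros((n_trials, n_features))
        X[:, 0] = rng.normal(size=n_trials)
        targs[r] = slope * X[:, 0]
        feats[r] = X
    return feats, targs


class TestCrossval:
    def test_perfectly_decodable(self, rng):
        feats, targs = _linear_problem(rng)
        rs = nv.crossval_svr(feats, targs)
        np.testing.assert_allclose(rs, 1.0, atol=1e-6)

    def test_no_leakage_from_test_fold(self, rng):
        """An outlier appended to the held-out run must not change the
        trained model's predictions for that run's original trials."""
        feats, targs = _linear_problem(rng, n_features=4)
        _, preds_clean = nv.crossval_svr(feats, targs, return_predictions=True)
        feats2 = {r: X.copy() for r, X in feats.items()}
        targs2 = {r: y.copy() for r, y in targs.items()}
        outlier = np.full((1, 4), 1e6)
        feats2[1] = np.vstack([feats2[1], outlier])
        targs2[1] = np.append(targs2[1], 1e6)
        _, preds_dirty = nv.crossval_svr(feats2, targs2,
                                         return_predictions=True)
        np.testing.assert_allclose(preds_dirty[1][:-1], preds_clean[1],
                                   rtol=1e-10)

    def test_constant_test_targets_recorded_missing(self, rng, caplog):
        feats, targs = _linear_problem(rng)
        targs[2] = np.zeros_like(targs[2])
        with caplog.at_level("WARNING", logger="nirsvig.decoding"):
            rs = nv.crossval_svr(feats, targs)
        assert np.isnan(rs[1]) and np.isfinite(rs[0])
        assert "undefined" in caplog.text

    def test_needs_two_runs(self, rng):
        with pytest.raises(ValueError, match="2 runs"):
            nv.crossval_svr({1: np.zeros((5, 2))}, {1: np.zeros(5)})


class TestGroupAccuracy:
    def test_zero_correlation_gives_zero_stat(self):
        r = np.zeros((4, 3, 6))
        res = nv.group_accuracy(r)
        assert np.all(res.per_subject_z == 0.0)
        assert np.all(res.group_t == 0.0) and np.all(res.group_p == 1.0)

    def test_unit_correlation_clipped_finite(self):
        r = np.ones((2, 1, 2))
        res = nv.group_accuracy(r)
        assert np.isfinite(res.per_subject_z).all()

    def test_closed_form_t(self):
        # per-subject z with mean 0.2 and sample sd 0.1 over n=8:
        # t = 0.2 / (0.1 / sqrt(8)) = 5.657
        u = np.array([-1.0, 1.0] * 4)
        u = u / u.std(ddof=1)
        z = 0.2 + 0.1 * u
        r = np.tanh(z)[:, None, None]
        res = nv.group_accuracy(r)
        assert res.group_t[0] == pytest.approx(0.2 / (0.1 / np.sqrt(8)),
                                               abs=1e-9)

    def test_window_times_are_centers(self):
        res = nv.group_accuracy(np.zeros((2, 40, 6)))
        spec = nv.WindowSpec()
        np.testing.assert_allclose(
            res.window_times,
            (nv.enumerate_windows(spec) + 3.0) / spec.fs)


class TestDecodeSubject:
    def test_recovers_coupled_signal(self, small_session, narrow_windows):
        """Strong RT coupling is decodable after onset, and the peak window
        falls in the hemodynamic response range."""
        _, data, _, norm = small_session
        folds = nv.decode_subject(norm, data.trials_rec, narrow_windows)
        z = np.nanmean(nv.fisher_z(folds), axis=1)
        times = nv.window_center_times(narrow_windows)
        assert z.max() > 0.3
        assert 3.0 <= times[np.argmax(z)] <= 9.0


class TestCouplingMonotonicity:
    def test_peak_accuracy_nondecreasing_in_coupling(self):
        """Group mean Fisher-Z at the peak window grows with the amplitude
        coupling strength (checked at coupling 0, small, large; fixed
        seeds, small sessions)."""
        peaks = []
        for beta in (0.0, 0.002, 0.005):
            beh = nv.BehaviorConfig(n_runs=3, n_trials_per_run=20)
            beh.vigilance.ar_coef = 0.0
            cfg = nv.PipelineConfig(behavior=beh,
                                    signal=nv.SignalConfig(coupling_beta=beta),
                                    n_subjects=2, master_seed=99)
            wspec = nv.WindowSpec(start_time=2.0, end_time=9.0, step=6)
            folds = []
            for s in range(2):
                data = nv.simulate_subject(cfg, s)
                _, norm = nv.preprocess_subject(data, cfg.filter)
                folds.append(nv.decode_subject(norm, data.trials_rec, wspec))
            res = nv.group_accuracy(np.asarray(folds), wspec)
            peaks.append(res.per_subject_z.mean(axis=0).max())
        assert peaks[0] <= peaks[1] <= peaks[2]
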