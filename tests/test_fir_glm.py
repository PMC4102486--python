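"""FIR design construction, OLS fitting, group statistics."""

import numpy as np
import pandas as pd
import pytest

import nirsvig as nv
from nirsvig.fir_glm import _fit_stacked, dct_drift_basis, round_half_away


FS = 6.25
N_SAMPLES = int(500 * FS)


def run_trials(n=40, rtc_pattern=(50.0, 50.0, -50.0, -50.0)):
    onsets = np.arange(10, 10 + 12.0 * n, 12.0)
    rtc = np.tile(rtc_pattern, n // len(rtc_pattern))
    return pd.DataFrame({
        "trial_index": np.arange(n), "run_id": 1, "onset": onsets,
        "duration": 0.2, "condition": ["congruent", "incongruent"] * (n // 2),
        "attention": "global", "correct": True, "rt": 550.0 + rtc,
        "rt_corrected": rtc, "vigilance": rtc})


@pytest.fixture(scope="module")
def design():
    return nv.build_design(run_trials(), N_SAMPLES, FS)


class TestRounding:
    def test_ties_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away([0.5, -0.5, 1.5, -1.5, 2.4, -2.4]),
            [1, -1, 2, -2, 2, -2])

    def test_printed_window_conversions(self):
        # the same convention reproduces both printed sample conversions
        assert round_half_away(-5.0 * FS) == -31
        assert round_half_away(14.7 * FS) == 92


class TestDesign:
    def test_24_task_regressors(self, design):
        assert len(design.task_columns) == 24

    def test_bin_spacing(self, design):
        assert design.bin_stride / FS == pytest.approx(0.96)
        # 12 bins span 0 .. 10.56 s post-onset
        assert (design.n_bins - 1) * design.bin_stride / FS == pytest.approx(10.56)

    def test_stick_counts(self, design):
        er_hr = design.matrix[:, design.columns("ER-HR")]
        assert (er_hr.sum(axis=0) <= 40).all()
        assert (er_hr.sum(axis=0) == 40).all()  # no truncation here

    def test_er_pm_is_rt_scaled_sticks(self):
        trials = run_trials()
        d = nv.build_design(trials, N_SAMPLES, FS)
        hr = d.matrix[:, d.columns("ER-HR")]
        pm = d.matrix[:, d.columns("ER-PM")]
        s0 = round_half_away(trials["onset"].to_numpy() * FS)
        for k in range(12):
            for s, rtc in zip(s0, trials["rt_corrected"]):
                assert hr[s + 6 * k, k] == 1.0
                assert pm[s + 6 * k, k] == rtc

    def test_incorrect_trials_no_modulation(self):
        trials = run_trials()
        trials.loc[0, "correct"] = False
        trials.loc[0, "rt"] = np.nan
        trials = nv.mean_correct_rt(trials)  # re-correct remaining cells
        d = nv.build_design(trials, N_SAMPLES, FS)
        s0 = round_half_away(trials.loc[0, "onset"] * FS)
        assert d.matrix[s0, d.columns("ER-HR")[0]] == 1.0
        assert d.matrix[s0, d.columns("ER-PM")[0]] == 0.0

    def test_dct_columns_orthogonal(self):
        B = dct_drift_basis(N_SAMPLES, FS, 128.0)
        G = B.T @ B
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()
        # all periods exceed the drift cutoff
        k = np.arange(1, B.shape[1] + 1)
        assert (2 * N_SAMPLES / (k * FS) > 128.0).all()

    def test_uncorrected_modulator_rejected(self):
        trials = run_trials()
        trials["rt_corrected"] = trials["rt_corrected"] + 30.0
        with pytest.raises(ValueError, match="mean-corrected"):
            nv.build_design(trials, N_SAMPLES, FS)

    def test_sticks_truncated_at_run_end_logged(self, caplog):
        trials = run_trials(n=4)
        short = int((trials["onset"].iloc[-1] + 2.0) * FS)
        with caplog.at_level("WARNING", logger="nirsvig.fir_glm"):
            d = nv.build_design(trials, short, FS)
        assert "truncated" in caplog.text
        assert d.matrix[:, d.columns("ER-HR")].sum() < 4 * 12


class TestFit:
    def test_noise_free_recovery(self, design, rng):
        true = rng.normal(size=(design.matrix.shape[1], 3))
        Y = design.matrix @ true
        res = _fit_stacked(Y, design.matrix, design.labels, FS, 6, 12)
        assert np.abs(res.betas - true[design.task_columns].T).max() < 1e-8

    def test_all_zero_data(self, design):
        Y = np.zeros((N_SAMPLES, 2))
        res = _fit_stacked(Y, design.matrix, design.labels, FS, 6, 12)
        assert np.all(res.betas == 0.0)

    def test_drift_in_dct_span_fully_absorbed(self, design, rng):
        Y = rng.normal(size=(N_SAMPLES, 1))
        b0 = _fit_stacked(Y, design.matrix, design.labels, FS, 6, 12).betas
        dct_cols = design.columns("DCT")[:2]
        drift = design.matrix[:, dct_cols] @ np.array([3.0, -2.0])
        b1 = _fit_stacked(Y + drift[:, None], design.matrix, design.labels,
                          FS, 6, 12).betas
        assert np.abs(b1 - b0).max() < 1e-6

    def test_arbitrary_slow_drift_matches_projection_oracle(self, design, rng):
        # OLS linearity: adding drift d changes betas by (X'X)^-1 X' d
        X = design.matrix
        Y = rng.normal(size=(N_SAMPLES, 1))
        t = np.arange(N_SAMPLES) / FS
        d = np.cos(2 * np.pi * t / 256.0)
        b0 = _fit_stacked(Y, X, design.labels, FS, 6, 12).betas
        b1 = _fit_stacked(Y + d[:, None], X, design.labels, FS, 6, 12).betas
        pred = np.linalg.lstsq(X, d, rcond=None)[0][design.task_columns]
        np.testing.assert_allclose((b1 - b0)[0], pred, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        trials = run_trials()
        trials["rt_corrected"] = 0.0  # ER-PM columns all zero
        d = nv.build_design(trials, N_SAMPLES, FS)
        with pytest.raises(np.linalg.LinAlgError, match="ER-PM"):
            _fit_stacked(np.zeros((N_SAMPLES, 1)), d.matrix, d.labels, FS, 6, 12)

    def test_run_stacking_block_diagonal_nuisance(self):
        cfg = nv.PipelineConfig(
            behavior=nv.BehaviorConfig(n_runs=2, n_trials_per_run=10),
            signal=nv.SignalConfig(white_sd=0.1), n_subjects=2, master_seed=5)
        data = nv.simulate_subject(cfg, 0)
        chromo, _ = nv.preprocess_subject(data, cfg.filter)
        res = nv.fit_subject_glm(chromo, data.trials_rec, cfg.fs)
        assert res["HbO"].betas.shape == (44, 24)
        assert res["HbO"].labels[:2] == ["ER-HR:1", "ER-HR:2"]


class TestGroupStats:
    def test_degenerate_zero_variance_rejected(self):
        betas = np.ones((8, 3, 24))
        with pytest.raises(ValueError, match="variance"):
            nv.group_stats(betas)

    def test_subject_count_guard(self):
        with pytest.raises(ValueError, match="2 subjects"):
            nv.group_stats(np.zeros((1, 3, 24)))

    def test_type_one_error_calibration(self, rng):
        betas = rng.normal(size=(8, 1000, 12))
        _, p = nv.group_stats(betas)
        frac = (p < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)


class TestParametricModulationRecovery:
    def test_erpm_profile_matches_noise_free_reference(self):
        """The ER-PM bin profile estimated from noisy data on responsive
        channels correlates >= 0.8 with the profile obtained by regressing
        the same subject's noise-free signal."""
        beh = nv.BehaviorConfig()
        beh.vigilance.ar_coef = 0.0
        quiet = dict(coupling_beta=0.005, responsive_channels=[0, 4, 8])
        profiles = {}
        for label, extra in (("clean", dict(cardiac_amp=0, respiratory_amp=0,
                                            mayer_amp=0, drift_slope_sd=0,
                                            white_sd=0)),
                             ("noisy", {})):
            cfg = nv.PipelineConfig(behavior=beh,
                                    signal=nv.SignalConfig(**quiet, **extra),
                                    n_subjects=2, master_seed=321)
            data = nv.simulate_subject(cfg, 0)
            chromo = {rid: nv.preprocess_run(a850, a760, data.channels,
                                             cfg.filter, normalize=False)
                      for rid, (a850, a760) in data.attenuation.items()}
            res = nv.fit_subject_glm(chromo, data.trials_rec, cfg.fs)
            mask = cfg.signal.responsive_mask(44)
            profiles[label] = res["HbO"].betas[mask, 12:24].mean(axis=0)
        r = np.corrcoef(profiles["clean"], profiles["noisy"])[0, 1]
        assert r >= 0.8
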