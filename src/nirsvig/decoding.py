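"""Sliding-window space-time decoding of single-trial reaction times.

For every position of a sliding window (width 7 samples, step 3, from -5 s
/ -31 samples to 14.7 s / 92 samples around stimulus onset at 6.25 Hz), the
preprocessed HbO + HbR series of all 44 channels are cut out around each
correct trial and flattened into an 88-channel x width feature vector.  A
linear-kernel support-vector regression predicts the trial's mean-corrected
reaction time under leave-one-run-out (6-fold) cross-validation; accuracy
per fold is the Pearson correlation between predicted and actual RTs.
Correlations are Fisher-Z transformed (z = atanh r), averaged per subject
across folds, and tested against zero across subjects per window with a
one-sample t-test (random-effects inference, df = n_subjects - 1).

Feature standardization uses training-fold statistics only, so no
information leaks from the held-out run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .fir_glm import round_half_away
from .signal_sim import Recording, DEFAULT_FS

logger = logging.getLogger("nirsvig.decoding")

R_CLIP = 1.0 - 1e-12


@dataclass
class WindowSpec:
    """Sliding-window geometry, times in seconds relative to onset."""

    start_time: float = -5.0
    end_time: float = 14.7
    width: int = 7
    step: int = 3
    fs: float = DEFAULT_FS

    @property
    def start_sample(self) -> int:
        return int(round_half_away(self.start_time * self.fs))

    @property
    def end_sample(self) -> int:
        return int(round_half_away(self.end_time * self.fs))

    def validate(self) -> None:
        if self.width < 1 or self.step < 1:
            raise ValueError("width and step must be >= 1")
        if self.end_sample - self.start_sample + 1 < self.width:
            raise ValueError("window range shorter than window width")


@dataclass
class SVRParams:
    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 0.1

    def make(self) -> SVR:
        return SVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon)


@dataclass
class DecodingResult:
    window_times: np.ndarray        # window-center seconds relative to onset
    window_starts: np.ndarray       # window start samples
    per_subject_z: np.ndarray       # subjects x windows
    group_t: np.ndarray
    group_p: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.per_subject_z.shape[0]):
            for w, t in enumerate(self.window_times):
                rows.append((t, s + 1, self.per_subject_z[s, w],
                             self.group_t[w], self.group_p[w]))
        return pd.DataFrame(rows, columns=["window_time_s", "subject",
                                           "mean_z", "group_t", "group_p"])


def enumerate_windows(spec: WindowSpec) -> np.ndarray:
    """Window start samples: start, start+step, ... while the window fits."""
    spec.validate()
    starts = np.arange(spec.start_sample,
                       spec.end_sample - spec.width + 2, spec.step)
    return starts


def window_center_times(spec: WindowSpec) -> np.ndarray:
    starts = enumerate_windows(spec)
    return (starts + (spec.width - 1) / 2.0) / spec.fs


def extract_features(hbo: Recording, hbr: Recording, trials: pd.DataFrame,
                     window_start: int, width: int,
                     reduce: str = "none"):
    """Trial x feature matrix for one run at one window position.

    Correct trials only.  For each trial the window
    ``[onset_sample + window_start, ... + width)`` is cut from both
    chromophores and concatenated: 88 feature channels x width samples
    flattened (``reduce="none"``), or the window mean per channel — 88
    features — for the time-frequency analysis (``reduce="mean"``).
    Trials whose window crosses the run boundary are dropped (logged).

    Returns ``(X, y, trial_index)`` with y the mean-corrected RTs.
    """
    ok = trials["correct"].to_numpy().astype(bool) \
        & np.isfinite(trials["rt_corrected"].to_numpy())
    sub = trials[ok]
    s0 = round_half_away(sub["onset"].to_numpy() * hbo.fs) + window_start
    inside = (s0 >= 0) & (s0 + width <= hbo.n_samples)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("window start %+d: dropped %d trial(s) at run boundary",
                    window_start, n_dropped)
    sub = sub[inside]
    s0 = s0[inside]
    if len(sub) == 0:
        raise ValueError(
            f"no trials remain for window start {window_start}; "
            "window exceeds every trial's run boundary"
        )
    feats = []
    for s in s0:
        seg = np.concatenate([hbo.data[:, s:s + width],
                              hbr.data[:, s:s + width]], axis=0)
        feats.append(seg.mean(axis=1) if reduce == "mean" else seg.ravel())
    X = np.asarray(feats)
    y = sub["rt_corrected"].to_numpy()
    return X, y, sub["trial_index"].to_numpy()


def crossval_svr(features: dict, targets: dict,
                 params: SVRParams | None = None,
                 return_predictions: bool = False):
    """Leave-one-run-out cross-validated SVR accuracy.

    ``features``/``targets`` map run_id -> (trials x features) / RT vector.
    Each run serves once as test set; features are standardized with
    training-fold statistics only.  Returns the per-fold Pearson correlation
    between predicted and actual targets (NaN when the test-fold correlation
    is undefined, e.g. constant targets; such folds are excluded from the
    subject mean).
    """
    params = params or SVRParams()
    run_ids = sorted(features)
    if len(run_ids) < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    rs = np.empty(len(run_ids))
    predictions = {}
    for i, test_run in enumerate(run_ids):
        train_X = np.vstack([features[r] for r in run_ids if r != test_run])
        train_y = np.concatenate([targets[r] for r in run_ids if r != test_run])
        scaler = StandardScaler()
        scale_X = scaler.fit_transform(train_X)
        test_X = scaler.transform(features[test_run])
        if params.kernel == "linear":
            # same libsvm model via a precomputed Gram matrix (BLAS) —
            # predictions are bit-identical and the fit is ~2x faster
            model = SVR(kernel="precomputed", C=params.C,
                        epsilon=params.epsilon)
            model.fit(scale_X @ scale_X.T, train_y)
            pred = model.predict(test_X @ scale_X.T)
        else:
            model = params.make()
            model.fit(scale_X, train_y)
            pred = model.predict(test_X)
        predictions[test_run] = pred
        y = targets[test_run]
        if len(y) < 2 or np.std(y) == 0 or np.std(pred) == 0:
            logger.warning("run %s: correlation undefined in test fold; "
                           "recorded as missing", test_run)
            rs[i] = np.nan
        else:
            rs[i] = np.corrcoef(pred, y)[0, 1]
    if return_predictions:
        return rs, predictions
    return rs


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing z = atanh(r), |r| clipped away from 1."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    return np.arctanh(r)


def decode_subject(recordings: dict, trials: pd.DataFrame,
                   window_spec: WindowSpec | None = None,
                   params: SVRParams | None = None,
                   reduce: str = "none",
                   rt_column: str = "rt_corrected") -> np.ndarray:
    """Per-window fold correlations for one subject.

    ``recordings`` maps run_id -> (Recording[HbO], Recording[HbR]), already
    preprocessed (drift-corrected, z-normalized) and with trial onsets on
    the recording clock.  Returns windows x folds correlation matrix.
    """
    window_spec = window_spec or WindowSpec()
    params = params or SVRParams()
    starts = enumerate_windows(window_spec)
    run_ids = sorted(recordings)
    out = np.empty((len(starts), len(run_ids)))
    for w, start in enumerate(starts):
        feats, targs = {}, {}
        for rid in run_ids:
            hbo, hbr = recordings[rid]
            run_trials = trials[trials["run_id"] == rid].copy()
            if rt_column != "rt_corrected":
                run_trials["rt_corrected"] = run_trials[rt_column]
            X, y, _ = extract_features(hbo, hbr, run_trials, int(start),
                                       window_spec.width, reduce=reduce)
            feats[rid], targs[rid] = X, y
        out[w] = crossval_svr(feats, targs, params)
    return out


def group_accuracy(per_fold_r: np.ndarray,
                   window_spec: WindowSpec | None = None) -> DecodingResult:
    """Group-level decoding result from per-subject fold correlations.

    ``per_fold_r`` is subjects x windows x folds.  Fold correlations are
    Fisher-Z transformed and averaged per subject (ignoring undefined
    folds), then tested against zero per window across subjects.
    """
    window_spec = window_spec or WindowSpec()
    per_fold_r = np.asarray(per_fold_r, dtype=float)
    if per_fold_r.ndim != 3:
        raise ValueError("per_fold_r must be subjects x windows x folds")
    if per_fold_r.shape[0] < 2:
        raise ValueError("group statistics require at least 2 subjects")
    z = fisher_z(per_fold_r)
    with np.errstate(invalid="ignore"):
        per_subject_z = np.nanmean(z, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_1samp(per_subject_z, 0.0, axis=0)
    # degenerate windows: identical z across subjects
    sd = per_subject_z.std(axis=0)
    mean = per_subject_z.mean(axis=0)
    exact_chance = (sd == 0) & (mean == 0)
    t = np.where(exact_chance, 0.0, t)
    p = np.where(exact_chance, 1.0, p)
    return DecodingResult(window_times=window_center_times(window_spec),
                          window_starts=enumerate_windows(window_spec),
                          per_subject_z=per_subject_z,
                          group_t=t, group_p=p,
                          meta={"n_subjects": per_fold_r.shape[0],
                                "df": per_fold_r.shape[0] - 1})
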