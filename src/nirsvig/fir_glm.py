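"""Finite-impulse-response GLM with reaction-time parametric modulation.

The event-related hemodynamic response (ER-HR) is modeled with 12 stick
regressors per trial, one every 6 samples (0.96 s at 6.25 Hz, spanning
0-10.56 s post-onset) — sticks rather than per-sample impulses because the
optical sampling rate is an order of magnitude above fMRI's.  A second set
of 12 regressors (ER-PM) carries each trial's mean-corrected reaction time
at the same samples, estimating the RT modulation of the response shape;
together 24 task regressors.  Slow drifts below 1/128 Hz are absorbed by a
discrete-cosine basis, with a per-run intercept.

Fitting is ordinary least squares per channel.  Runs are stacked: task
columns are shared across runs, drift/intercept columns are block-diagonal
per run (run-wise nuisance regression).  Group inference is a one-sample
t-test of each beta against zero across subjects (df = n_subjects - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signal_sim import Recording

logger = logging.getLogger("nirsvig.fir_glm")

N_BINS_DEFAULT = 12
STRIDE_DEFAULT = 6
DRIFT_PERIOD_DEFAULT = 128.0


def round_half_away(x) -> np.ndarray:
    """Nearest-sample rounding, ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def dct_drift_basis(n_samples: int, fs: float,
                    period: float = DRIFT_PERIOD_DEFAULT) -> np.ndarray:
    """Discrete-cosine drift columns with period > ``period`` seconds.

    Column k (k = 1..K) is ``cos(pi * k * (2n + 1) / (2N))``; K is the
    largest order whose period ``2N/(k*fs)`` still exceeds ``period``.  The
    constant k = 0 term is excluded (a separate intercept exists per run).
    Columns are mutually orthogonal.
    """
    K = int(np.floor(2.0 * n_samples / (fs * period)))
    n = np.arange(n_samples)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_samples))
            for k in range(1, K + 1)]
    if not cols:
        return np.empty((n_samples, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # samples x regressors
    labels: list                # per-column labels
    fs: float
    bin_stride: int
    n_bins: int
    run_id: int | None = None

    @property
    def task_columns(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels)
                         if l.startswith("ER-")])

    def columns(self, prefix: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels)
                         if l.startswith(prefix)])


@dataclass
class GLMResult:
    betas: np.ndarray           # channels x n_task_regressors
    labels: list
    residual_variance: np.ndarray
    dof: int
    bin_times: np.ndarray       # seconds post-onset per bin
    meta: dict = field(default_factory=dict)


def build_design(trials: pd.DataFrame, n_samples: int, fs: float,
                 n_bins: int = N_BINS_DEFAULT, stride: int = STRIDE_DEFAULT,
                 drift_period: float = DRIFT_PERIOD_DEFAULT,
                 modulator_tol: float = 1e-6,
                 run_id: int | None = None) -> DesignMatrix:
    """Design matrix for one run: 12 ER-HR sticks + 12 ER-PM + DCT + const.

    Each trial with onset sample ``s0`` (nearest-sample rounding) places a
    unit stick at ``s0 + k*stride`` into ER-HR column k; the ER-PM column k
    holds the trial's mean-corrected RT at the same sample (correct trials
    only — error trials keep their ER-HR sticks but contribute zero to
    ER-PM).  Sticks of overlapping trials add.  Sticks that would fall past
    the end of the run are truncated with a logged warning.
    """
    onsets = trials["onset"].to_numpy()
    s0 = round_half_away(onsets * fs)
    if (s0 < 0).any() or (s0 >= n_samples).any():
        raise ValueError("trial onsets fall outside the run")
    rtc = trials["rt_corrected"].to_numpy()
    correct = trials["correct"].to_numpy().astype(bool) & np.isfinite(rtc)
    # modulators must be mean-corrected per condition cell
    for cond, sub in trials.groupby("condition"):
        ok = sub["correct"].to_numpy().astype(bool) & np.isfinite(sub["rt_corrected"])
        if ok.any():
            m = sub.loc[ok, "rt_corrected"].mean()
            if abs(m) > modulator_tol:
                raise ValueError(
                    f"RT modulator not mean-corrected (condition {cond!r}: "
                    f"cell mean {m:.3g} ms); run mean_correct_rt first"
                )

    er_hr = np.zeros((n_samples, n_bins))
    er_pm = np.zeros((n_samples, n_bins))
    n_truncated = 0
    for i, s in enumerate(s0):
        for k in range(n_bins):
            idx = s + k * stride
            if idx >= n_samples:
                n_truncated += 1
                continue
            er_hr[idx, k] += 1.0
            if correct[i]:
                er_pm[idx, k] += rtc[i]
    if n_truncated:
        logger.warning("truncated %d sticks beyond run end", n_truncated)

    drift = dct_drift_basis(n_samples, fs, drift_period)
    const = np.ones((n_samples, 1))
    X = np.hstack([er_hr, er_pm, drift, const])
    labels = ([f"ER-HR:{k + 1}" for k in range(n_bins)]
              + [f"ER-PM:{k + 1}" for k in range(n_bins)]
              + [f"DCT:{k + 1}" for k in range(drift.shape[1])]
              + ["const"])
    return DesignMatrix(X, labels, fs, stride, n_bins, run_id=run_id)


def _check_rank(X: np.ndarray, labels: list) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [labels[i] for i in np.where(bad)[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {cols}"
        )


def fit_glm(rec: Recording, design: DesignMatrix) -> GLMResult:
    """OLS fit of one run's recording against its design matrix."""
    return _fit_stacked(rec.data.T, design.matrix, design.labels,
                        design.fs, design.bin_stride, design.n_bins)


def _fit_stacked(Y: np.ndarray, X: np.ndarray, labels: list, fs: float,
                 stride: int, n_bins: int) -> GLMResult:
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design rows must equal recording samples")
    _check_rank(X, labels)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = Y.shape[0] - X.shape[1]
    resvar = (resid ** 2).sum(axis=0) / max(dof, 1)
    task = np.array([i for i, l in enumerate(labels) if l.startswith("ER-")])
    task_labels = [labels[i] for i in task]
    bin_times = np.arange(n_bins) * stride / fs
    return GLMResult(betas=beta[task].T, labels=task_labels,
                     residual_variance=resvar, dof=dof, bin_times=bin_times)


def fit_subject_glm(recordings: dict, trials: pd.DataFrame, fs: float,
                    n_bins: int = N_BINS_DEFAULT, stride: int = STRIDE_DEFAULT,
                    drift_period: float = DRIFT_PERIOD_DEFAULT) -> dict:
    """Fit the FIR GLM across a subject's runs for both chromophores.

    ``recordings`` maps run_id -> (Recording[HbO], Recording[HbR]) with
    trial onsets already on the recording clock.  Task columns are shared
    across runs; drift and intercept columns are block-diagonal per run.
    Returns ``{"HbO": GLMResult, "HbR": GLMResult}``.
    """
    run_ids = sorted(recordings)
    designs = []
    for rid in run_ids:
        hbo, _ = recordings[rid]
        run_trials = trials[trials["run_id"] == rid]
        designs.append(build_design(run_trials, hbo.n_samples, fs,
                                    n_bins, stride, drift_period, run_id=rid))
    X, labels = stack_run_designs(designs)
    out = {}
    for ci, chromo in enumerate(("HbO", "HbR")):
        Y = np.vstack([recordings[rid][ci].data.T for rid in run_ids])
        out[chromo] = _fit_stacked(Y, X, labels, fs, stride, n_bins)
    return out


def stack_run_designs(designs: list) -> tuple[np.ndarray, list]:
    """Concatenate task columns, block-diagonalize nuisance columns."""
    n_task = designs[0].n_bins * 2
    total_rows = sum(d.matrix.shape[0] for d in designs)
    nuis_sizes = [d.matrix.shape[1] - n_task for d in designs]
    X = np.zeros((total_rows, n_task + sum(nuis_sizes)))
    labels = list(designs[0].labels[:n_task])
    r0, c0 = 0, n_task
    for d in designs:
        rows = d.matrix.shape[0]
        X[r0:r0 + rows, :n_task] = d.matrix[:, :n_task]
        nn = d.matrix.shape[1] - n_task
        X[r0:r0 + rows, c0:c0 + nn] = d.matrix[:, n_task:]
        labels += [f"run{d.run_id}:{l}" for l in d.labels[n_task:]]
        r0 += rows
        c0 += nn
    return X, labels


def group_stats(betas: np.ndarray):
    """One-sample t-test of betas against 0 across subjects.

    ``betas`` is subjects x channels x regressors (or any shape with
    subjects first).  Returns (t, p) with df = n_subjects - 1, two-sided.
    Exactly constant nonzero betas across subjects (sd = 0) are a degenerate
    input and raise.
    """
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[0]
    if n < 2:
        raise ValueError("group statistics require at least 2 subjects")
    sd = betas.std(axis=0)
    mean = betas.mean(axis=0)
    if np.any((sd == 0) & (mean != 0)):
        raise ValueError("zero between-subject variance with nonzero mean: "
                         "t statistic undefined")
    t, p = stats.ttest_1samp(betas, 0.0, axis=0)
    return t, p
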