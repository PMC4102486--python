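"""Stroop experiment design and reaction-time behavior simulation.

Generates the event structure of a global-local Stroop session — 6 runs of
60 trials (30 congruent / 30 incongruent), inter-trial intervals drawn from
a truncated shifted exponential on [7, 12] s with mean 7.9 s — together with
per-trial reaction times built from a base RT, a congruency effect, a slow
"vigilance" fluctuation process sampled at trial onsets, and i.i.d. noise.
The vigilance component is returned as ground truth so downstream recovery
tests can key off it.

Trial tables are plain :class:`pandas.DataFrame` objects with BIDS-events-like
columns (onset in seconds, condition, correctness, RT in milliseconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

TRIAL_COLUMNS = [
    "trial_index",
    "run_id",
    "onset",
    "duration",
    "condition",
    "attention",
    "correct",
    "rt",
    "rt_corrected",
    "vigilance",
]

CONDITIONS = ("congruent", "incongruent")


@dataclass
class VigilanceProcess:
    """Slow trial-to-trial RT fluctuation model.

    ``kind="ar1"``: first-order autoregression over the trial sequence with
    coefficient ``ar_coef`` and innovation standard deviation
    ``ar_innovation_sd`` (ms); the stationary sd is
    ``ar_innovation_sd / sqrt(1 - ar_coef**2)``.

    ``kind="sinusoid"``: a mixture of sinusoids in absolute session time,
    with ``frequencies_hz`` and ``amplitudes_ms`` and random phases.
    """

    kind: str = "ar1"
    ar_coef: float = 0.8
    ar_innovation_sd: float = 30.0
    frequencies_hz: Sequence[float] = field(default_factory=lambda: [0.01, 0.02])
    amplitudes_ms: Sequence[float] = field(default_factory=lambda: [40.0, 25.0])

    def __post_init__(self):
        self.frequencies_hz = list(self.frequencies_hz)
        self.amplitudes_ms = list(self.amplitudes_ms)

    def validate(self) -> None:
        if self.kind not in ("ar1", "sinusoid"):
            raise ValueError(f"unknown vigilance process kind: {self.kind!r}")
        if self.kind == "ar1" and not (-1.0 < self.ar_coef < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.kind == "sinusoid" and len(self.frequencies_hz) != len(self.amplitudes_ms):
            raise ValueError("frequencies and amplitudes must have equal length")


@dataclass
class BehaviorConfig:
    """Design and behavior parameters of the simulated Stroop session."""

    n_runs: int = 6
    n_trials_per_run: int = 60
    iti_min: float = 7.0
    iti_max: float = 12.0
    iti_mean: float = 7.9
    stimulus_duration: float = 0.2
    rt_base: float = 550.0
    congruency_effect: float = 60.0
    # per-subject mean error counts of 2.75 / 7.75 out of 180 trials per
    # condition across a session
    error_rate_congruent: float = 2.75 / 180.0
    error_rate_incongruent: float = 7.75 / 180.0
    vigilance: VigilanceProcess = field(default_factory=VigilanceProcess)
    rt_noise_sd: float = 40.0
    attention_swapped: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_run % 2:
            raise ValueError(
                f"n_trials_per_run={self.n_trials_per_run} is odd; "
                "conditions cannot be balanced"
            )
        if not (self.iti_min <= self.iti_mean <= self.iti_max):
            raise ValueError("require iti_min <= iti_mean <= iti_max")
        for name in ("error_rate_congruent", "error_rate_incongruent"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        self.vigilance.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def solve_iti_rate(iti_min: float, iti_max: float, iti_mean: float,
                   tol: float = 1e-12) -> float:
    """Rate of the truncated shifted exponential matching a target mean.

    The ITI law is ``iti_min + Y`` where ``Y`` has density proportional to
    ``exp(-rate * y)`` on ``[0, L]``, ``L = iti_max - iti_min``.  The
    truncated mean ``E[Y] = 1/rate - L/(exp(rate*L) - 1)`` decreases from
    ``L/2`` (rate -> 0, uniform) to 0 (rate -> inf), so a decaying
    exponential can realise any mean in ``(iti_min, (iti_min+iti_max)/2]``.

    Returns 0.0 at the uniform limit.  Raises ``ValueError`` naming the
    feasible mean interval otherwise.
    """
    L = iti_max - iti_min
    target = iti_mean - iti_min
    midpoint = L / 2.0
    if abs(target - midpoint) <= tol:
        return 0.0
    if not (0.0 < target < midpoint):
        raise ValueError(
            f"iti_mean={iti_mean} infeasible for an exponential decay on "
            f"[{iti_min}, {iti_max}]; feasible means lie in "
            f"({iti_min}, {(iti_min + iti_max) / 2.0}]"
        )

    def mean_minus_target(rate: float) -> float:
        x = rate * L
        tail = 0.0 if x > 700.0 else L / math.expm1(x)
        return 1.0 / rate - tail - target

    # bracket: small rate -> mean near L/2 (> target); large rate -> mean ~ 1/rate
    lo, hi = 1e-9, 2.0 / target + 10.0
    while mean_minus_target(hi) > 0:
        hi *= 2.0
    return float(brentq(mean_minus_target, lo, hi, xtol=1e-14, rtol=1e-15))


def sample_itis(n: int, cfg: BehaviorConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` inter-trial intervals (seconds) from the configured law."""
    rate = solve_iti_rate(cfg.iti_min, cfg.iti_max, cfg.iti_mean)
    L = cfg.iti_max - cfg.iti_min
    u = rng.random(n)
    if rate == 0.0:
        y = u * L
    else:
        # inverse CDF of the truncated exponential on [0, L]
        y = -np.log1p(-u * (-math.expm1(-rate * L))) / rate
    return cfg.iti_min + y


def generate_trials(cfg: BehaviorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate the trial table: onsets, balanced conditions, attention blocks.

    Attention is "global" for the first half of the runs and "local" for the
    second half (swapped when ``cfg.attention_swapped``), mirroring the
    counterbalancing of the task.  Onsets accumulate the sampled ITIs, so a
    run's expected span is ``n_trials_per_run * iti_mean`` seconds.
    """
    cfg.validate()
    half = cfg.n_trials_per_run // 2
    rows = []
    trial_index = 0
    first_half_attention = "local" if cfg.attention_swapped else "global"
    second_half_attention = "global" if cfg.attention_swapped else "local"
    for run in range(1, cfg.n_runs + 1):
        itis = sample_itis(cfg.n_trials_per_run, cfg, rng)
        onsets = np.cumsum(itis)
        conditions = np.array(["congruent"] * half + ["incongruent"] * half)
        rng.shuffle(conditions)
        attention = (first_half_attention if run <= cfg.n_runs // 2
                     else second_half_attention)
        for onset, cond in zip(onsets, conditions):
            rows.append((trial_index, run, float(onset), cfg.stimulus_duration,
                         cond, attention))
            trial_index += 1
    df = pd.DataFrame(rows, columns=["trial_index", "run_id", "onset",
                                     "duration", "condition", "attention"])
    df["correct"] = True
    df["rt"] = np.nan
    df["rt_corrected"] = np.nan
    df["vigilance"] = np.nan
    return df


def sample_vigilance(n: int, onsets_abs: np.ndarray, proc: VigilanceProcess,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample the slow vigilance fluctuation (ms) at ``n`` trial onsets.

    For the AR(1) kind the process runs over the trial sequence (index time);
    for the sinusoid kind it is evaluated at absolute session time.
    """
    proc.validate()
    if proc.kind == "ar1":
        rho, s = proc.ar_coef, proc.ar_innovation_sd
        v = np.empty(n)
        stat_sd = s / math.sqrt(1.0 - rho * rho)
        v[0] = rng.normal(0.0, stat_sd)
        innov = rng.normal(0.0, s, size=n - 1)
        for i in range(1, n):
            v[i] = rho * v[i - 1] + innov[i - 1]
        return v
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(proc.frequencies_hz))
    v = np.zeros(n)
    for f, a, ph in zip(proc.frequencies_hz, proc.amplitudes_ms, phases):
        v += a * np.sin(2.0 * np.pi * f * onsets_abs + ph)
    return v


def generate_rts(trials: pd.DataFrame, cfg: BehaviorConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Attach reaction times, correctness and the vigilance ground truth.

    ``rt = rt_base + congruency_effect * [incongruent] + v(onset) + noise``
    where ``v`` is the configured slow process.  Correctness is Bernoulli per
    condition; missed/incorrect trials carry no RT (the analyses use correct
    trials only) but keep their design slot.
    """
    cfg.validate()
    trials = trials.copy()
    n = len(trials)
    # absolute session time for time-based processes: stack runs end to end
    run_span = cfg.n_trials_per_run * cfg.iti_mean
    onsets_abs = trials["onset"].to_numpy() + (trials["run_id"].to_numpy() - 1) * run_span
    v = sample_vigilance(n, onsets_abs, cfg.vigilance, rng)
    incong = (trials["condition"] == "incongruent").to_numpy()
    rt = (cfg.rt_base + cfg.congruency_effect * incong + v
          + rng.normal(0.0, cfg.rt_noise_sd, size=n))
    err_p = np.where(incong, cfg.error_rate_incongruent, cfg.error_rate_congruent)
    correct = rng.random(n) >= err_p
    trials["vigilance"] = v
    trials["correct"] = correct
    trials["rt"] = np.where(correct, rt, np.nan)
    trials["rt_corrected"] = np.nan
    return trials


def mean_correct_rt(trials: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Mean-correct RTs per (run, condition) cell over correct trials.

    After correction the mean corrected RT of every cell is zero, so the
    corrected values carry no congruency information — only fluctuations
    around each cell's average, the operational vigilance measure.
    Idempotent: correcting an already-corrected table changes nothing.
    """
    trials = trials.copy()
    corrected = np.full(len(trials), np.nan)
    for (run, cond), idx in trials.groupby(["run_id", "condition"]).groups.items():
        sub = trials.loc[idx]
        ok = sub["correct"].to_numpy() & np.isfinite(sub["rt"].to_numpy())
        if not ok.any():
            raise ValueError(
                f"cell (run={run}, condition={cond}) has no correct trials; "
                "cannot mean-correct"
            )
        cell_mean = sub.loc[ok, "rt"].mean()
        pos = trials.index.get_indexer(sub.index[ok])
        corrected[pos] = sub.loc[ok, "rt"].to_numpy() - cell_mean
    trials["rt_corrected"] = corrected
    return trials


def simulate_behavior(cfg: BehaviorConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full behavioral simulation: trials -> RTs -> mean correction."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trials = generate_trials(cfg, rng)
    trials = generate_rts(trials, cfg, rng)
    return mean_correct_rt(trials)
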