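"""Forward model: RT-coupled hemodynamics, physiological noise, optics.

Builds per-channel oxy-/deoxyhemoglobin (HbO/HbR) concentration-change time
series for each run of a simulated session, then maps them to two-wavelength
optical attenuation changes with the (forward) modified Beer-Lambert law.

The task-evoked HbO response on responsive channels is a double-gamma
hemodynamic response whose single-trial amplitude is modulated by the
mean-corrected reaction time, ``1 + coupling_beta * rt_corrected``, with an
optional RT-dependent peak-latency shift.  HbR is a scaled, lagged mirror of
the HbO component (smaller magnitude, opposite sign).  Physiological noise
comprises cardiac, respiratory and Mayer-wave sinusoids with channel-random
phases, a channel-random linear drift, and white noise.

Default 44-channel geometry: 16 sources x 16 detectors, source-detector
distances in [2, 3] cm.  Default sampling rate 6.25 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import quad

DEFAULT_FS = 6.25

#: molar extinction coefficients (1/(mM*cm)); rows = wavelengths (850, 760 nm),
#: columns = chromophores (HbO, HbR).  Standard tabulated values; all
#: correctness guarantees hold for any nonsingular positive matrix.
EXTINCTION_DEFAULT = np.array([[1.058, 0.691],
                               [0.586, 1.548]])

#: differential pathlength factors per wavelength (850, 760 nm)
DPF_DEFAULT = (5.8, 6.4)

WAVELENGTHS_NM = (850, 760)


@dataclass
class Recording:
    """Multi-channel time series of one run.

    ``data`` is channels x samples; ``signal_kind`` is one of
    ``"attenuation@850nm"``, ``"attenuation@760nm"``, ``"HbO"``, ``"HbR"``.
    Attenuation is dimensionless delta-OD; chromophore series are
    concentration x pathlength changes (mM*cm-equivalent).
    """

    data: np.ndarray
    fs: float
    run_id: int
    signal_kind: str
    units: str = ""
    channel_ids: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be channels x samples")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, signal_kind: str | None = None,
                  units: str | None = None) -> "Recording":
        return Recording(data=np.asarray(data, dtype=float), fs=self.fs,
                         run_id=self.run_id,
                         signal_kind=signal_kind or self.signal_kind,
                         units=self.units if units is None else units,
                         channel_ids=list(self.channel_ids),
                         meta=dict(self.meta))


def make_channel_table(n_channels: int = 44, n_sources: int = 16,
                       n_detectors: int = 16, distance_range=(2.0, 3.0),
                       seed: int = 0) -> pd.DataFrame:
    """Deterministic 44-channel source-detector geometry fixture.

    Channels are unique source-detector pairs with distances drawn uniformly
    in ``distance_range`` (cm).  True scalp coordinates are out of scope; the
    table carries exactly what the Beer-Lambert model needs.
    """
    if n_channels > n_sources * n_detectors:
        raise ValueError("more channels than source-detector pairs")
    rng = np.random.default_rng(seed)
    pairs = [(s, d) for s in range(1, n_sources + 1)
             for d in range(1, n_detectors + 1)]
    chosen = rng.choice(len(pairs), size=n_channels, replace=False)
    chosen.sort()
    lo, hi = distance_range
    dist = rng.uniform(lo, hi, size=n_channels)
    rows = [(f"S{pairs[i][0]}-D{pairs[i][1]}", pairs[i][0], pairs[i][1], d)
            for i, d in zip(chosen, dist)]
    return pd.DataFrame(rows, columns=["channel_id", "source_id",
                                       "detector_id", "distance_cm"])


@dataclass
class SignalConfig:
    # double-gamma HRF: shape = delay/dispersion, scale = dispersion (s);
    # undershoot subtracted with amplitude 1/ratio
    hrf_peak_delay: float = 7.0
    hrf_undershoot_delay: float = 16.0
    hrf_peak_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_ratio: float = 6.0
    hrf_duration: float = 30.0
    response_amplitude: float = 1.0
    coupling_beta: float = 0.002   # fractional amplitude change per ms corrected RT
    latency_beta: float = 0.0      # s peak shift per ms corrected RT
    hbr_ratio: float = -0.35
    hbr_lag: float = 1.0
    cardiac_freq: float = 1.1
    cardiac_amp: float = 0.4
    respiratory_freq: float = 0.3
    respiratory_amp: float = 0.15
    mayer_freq: float = 0.1
    mayer_amp: float = 0.1
    drift_slope_sd: float = 0.003  # per second, channel-random
    white_sd: float = 0.25
    responsive_channels: list | None = None  # channel indices; None -> every 4th
    seed: int = 0

    def validate(self) -> None:
        if self.hrf_peak_dispersion <= 0 or self.hrf_undershoot_dispersion <= 0:
            raise ValueError("HRF dispersion parameters must be positive")
        for name in ("cardiac_amp", "respiratory_amp", "mayer_amp",
                     "white_sd", "drift_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def responsive_mask(self, n_channels: int) -> np.ndarray:
        mask = np.zeros(n_channels, dtype=bool)
        if self.responsive_channels is None:
            mask[::4] = True
        else:
            mask[np.asarray(self.responsive_channels, dtype=int)] = True
        return mask

    def to_dict(self) -> dict:
        return asdict(self)


def hrf_function(cfg: SignalConfig):
    """Continuous double-gamma HRF as a vectorized callable of time (s)."""
    cfg.validate()
    from scipy.stats import gamma as gamma_dist
    a1 = cfg.hrf_peak_delay / cfg.hrf_peak_dispersion
    a2 = cfg.hrf_undershoot_delay / cfg.hrf_undershoot_dispersion
    s1, s2 = cfg.hrf_peak_dispersion, cfg.hrf_undershoot_dispersion
    ratio = cfg.hrf_ratio

    dur = cfg.hrf_duration

    def h(t):
        # finite support [0, hrf_duration): the residual tail is < 1e-6 of
        # the peak and truncating keeps non-overlapping trials exactly so
        t = np.asarray(t, dtype=float)
        out = (gamma_dist.pdf(t, a1, scale=s1)
               - gamma_dist.pdf(t, a2, scale=s2) / ratio)
        return np.where((t >= 0) & (t < dur), out, 0.0)

    return h


def hrf_kernel(cfg: SignalConfig, fs: float, normalize: bool = True) -> np.ndarray:
    """Sample the HRF at ``fs`` over ``hrf_duration`` seconds.

    With ``normalize=True`` the kernel peak is scaled to 1 so the response
    amplitude parameter is in signal units.  The default shape peaks at
    ~5 s and covers 30 s including the undershoot.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    h = hrf_function(cfg)
    t = np.arange(0.0, cfg.hrf_duration, 1.0 / fs)
    k = h(t)
    if normalize:
        peak = _hrf_peak_value(cfg)
        if peak > 0:
            k = k / peak
    return k


def _hrf_peak_value(cfg: SignalConfig) -> float:
    h = hrf_function(cfg)
    t = np.linspace(0.0, cfg.hrf_duration, 20001)
    return float(np.max(h(t)))


def hrf_integral(cfg: SignalConfig) -> float:
    """Numerical integral of the continuous double-gamma over its support."""
    h = hrf_function(cfg)
    val, _ = quad(lambda t: float(h(t)), 0.0, cfg.hrf_duration, limit=200)
    return val


def _task_component(t: np.ndarray, trials: pd.DataFrame,
                    cfg: SignalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Summed single-trial responses on the run's time grid.

    Returns (signal, per-trial amplitudes).  Each trial contributes
    ``amp * h(t - onset - latency_shift)`` where ``amp`` is
    ``1 + coupling_beta * rt_corrected`` (1 for trials without a corrected
    RT — misses still evoke a response).
    """
    h = hrf_function(cfg)
    peak = _hrf_peak_value(cfg)
    sig = np.zeros_like(t)
    rtc = trials["rt_corrected"].to_numpy()
    amps = np.where(np.isfinite(rtc), 1.0 + cfg.coupling_beta * rtc, 1.0)
    lats = np.where(np.isfinite(rtc), cfg.latency_beta * rtc, 0.0)
    for onset, amp, lat in zip(trials["onset"].to_numpy(), amps, lats):
        sig += amp * h(t - onset - lat)
    return cfg.response_amplitude * sig / peak, amps


def _noise(n_channels: int, t: np.ndarray, cfg: SignalConfig,
           rng: np.random.Generator) -> np.ndarray:
    noise = np.zeros((n_channels, t.size))
    for freq, amp in ((cfg.cardiac_freq, cfg.cardiac_amp),
                      (cfg.respiratory_freq, cfg.respiratory_amp),
                      (cfg.mayer_freq, cfg.mayer_amp)):
        if amp > 0:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_channels)
            noise += amp * np.sin(2.0 * np.pi * freq * t[None, :]
                                  + phases[:, None])
    if cfg.drift_slope_sd > 0:
        slopes = rng.normal(0.0, cfg.drift_slope_sd, size=n_channels)
        noise += slopes[:, None] * t[None, :]
    if cfg.white_sd > 0:
        noise += rng.normal(0.0, cfg.white_sd, size=(n_channels, t.size))
    return noise


def simulate_chromophores(trials: pd.DataFrame, channels: pd.DataFrame,
                          cfg: SignalConfig, rng: np.random.Generator,
                          fs: float = DEFAULT_FS,
                          pre_time: float = 6.0):
    """Simulate HbO/HbR recordings for every run in ``trials``.

    Returns ``(recordings, truth)`` where ``recordings`` maps
    ``run_id -> (Recording[HbO], Recording[HbR])`` and ``truth`` is a
    DataFrame of per-trial ground-truth response amplitudes
    (``1 + coupling_beta * rt_corrected``) for recovery tests.

    ``pre_time`` seconds of recording precede the first onset so that
    pre-stimulus decoding windows exist; each run extends one kernel length
    past its last onset.
    """
    cfg.validate()
    n_channels = len(channels)
    mask = cfg.responsive_mask(n_channels)
    if cfg.coupling_beta != 0.0 and not mask.any():
        raise ValueError("RT coupling requested but no responsive channels")
    ch_ids = channels["channel_id"].tolist()
    recordings = {}
    truth_rows = []
    for run_id, run_trials in trials.groupby("run_id"):
        run_trials = run_trials.copy()
        # shift onsets so the run starts pre_time s before the first trial
        run_trials["onset"] = run_trials["onset"].to_numpy() + pre_time \
            - run_trials["onset"].min()
        duration = run_trials["onset"].max() + cfg.hrf_duration + 2.0
        n_samples = int(np.ceil(duration * fs))
        t = np.arange(n_samples) / fs

        task, amps = _task_component(t, run_trials, cfg)
        task_lag, _ = _task_component(t - cfg.hbr_lag, run_trials, cfg)

        hbo = np.where(mask[:, None], task[None, :], 0.0) \
            + _noise(n_channels, t, cfg, rng)
        hbr = np.where(mask[:, None], cfg.hbr_ratio * task_lag[None, :], 0.0) \
            + _noise(n_channels, t, cfg, rng)

        meta = {"onset_shift": float(pre_time), "n_trials": len(run_trials)}
        recordings[run_id] = (
            Recording(hbo, fs, run_id, "HbO", units="mM*cm", channel_ids=ch_ids,
                      meta=dict(meta)),
            Recording(hbr, fs, run_id, "HbR", units="mM*cm", channel_ids=ch_ids,
                      meta=dict(meta)),
        )
        for ti, onset, amp in zip(run_trials["trial_index"], run_trials["onset"], amps):
            truth_rows.append((ti, run_id, float(onset), float(amp)))
    truth = pd.DataFrame(truth_rows, columns=["trial_index", "run_id",
                                              "onset_in_recording", "amplitude"])
    return recordings, truth


def shift_onsets_to_recording(trials: pd.DataFrame, pre_time: float = 6.0) -> pd.DataFrame:
    """Re-express trial onsets on each run's recording clock (see
    :func:`simulate_chromophores`)."""
    out = []
    for _, run_trials in trials.groupby("run_id"):
        rt = run_trials.copy()
        rt["onset"] = rt["onset"].to_numpy() + pre_time - rt["onset"].min()
        out.append(rt)
    return pd.concat(out).sort_values("trial_index").reset_index(drop=True)


def _check_extinction(extinction: np.ndarray) -> np.ndarray:
    E = np.asarray(extinction, dtype=float)
    if E.shape != (2, 2):
        raise ValueError("extinction matrix must be 2x2 (wavelengths x chromophores)")
    if abs(np.linalg.det(E)) < 1e-12 * np.abs(E).max() ** 2:
        raise ValueError("extinction matrix is singular: chromophores unidentifiable")
    return E


def forward_beer_lambert(hbo: Recording, hbr: Recording, channels: pd.DataFrame,
                         extinction: np.ndarray = EXTINCTION_DEFAULT,
                         dpf=DPF_DEFAULT) -> tuple[Recording, Recording]:
    """Map chromophore changes to attenuation changes at the two wavelengths.

    ``dA(lambda, ch, t) = [eps_HbO(lambda)*dHbO + eps_HbR(lambda)*dHbR]
    * distance(ch) * DPF(lambda)`` — the forward direction of the modified
    Beer-Lambert law used in preprocessing.
    """
    E = _check_extinction(extinction)
    if hbo.data.shape != hbr.data.shape:
        raise ValueError("HbO and HbR recordings must be aligned")
    dist = channels["distance_cm"].to_numpy()[:, None]
    a = []
    for w in range(2):
        da = (E[w, 0] * hbo.data + E[w, 1] * hbr.data) * dist * dpf[w]
        a.append(da)
    meta = dict(hbo.meta)
    meta.update({"extinction": np.asarray(extinction).tolist(),
                 "dpf": list(dpf)})
    rec850 = Recording(a[0], hbo.fs, hbo.run_id, "attenuation@850nm",
                       units="dOD", channel_ids=list(hbo.channel_ids), meta=meta)
    rec760 = Recording(a[1], hbo.fs, hbo.run_id, "attenuation@760nm",
                       units="dOD", channel_ids=list(hbo.channel_ids),
                       meta=dict(meta))
    return rec850, rec760
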