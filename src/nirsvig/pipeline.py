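"""End-to-end pipeline: simulate -> preprocess -> GLM -> decode -> band map.

A :class:`PipelineConfig` bundles every stage's parameters and a master
seed.  Per-subject random generators are derived with
``numpy.random.SeedSequence((master_seed, subject_index))`` — a counter
style scheme, so enlarging the group never perturbs existing subjects'
data.  Identical configuration and seed reproduce the result bundle
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import design_sim, signal_sim, preprocess, fir_glm, decoding, timefreq
from .design_sim import BehaviorConfig
from .signal_sim import (SignalConfig, make_channel_table, DEFAULT_FS,
                         EXTINCTION_DEFAULT, DPF_DEFAULT)
from .preprocess import FilterSpec
from .decoding import WindowSpec, SVRParams
from .timefreq import BandSpec

logger = logging.getLogger("nirsvig.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and subject context."""


@dataclass
class GLMParams:
    n_bins: int = 12
    stride: int = 6
    drift_period: float = 128.0


@dataclass
class PipelineConfig:
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    glm: GLMParams = field(default_factory=GLMParams)
    window: WindowSpec = field(default_factory=WindowSpec)
    svr: SVRParams = field(default_factory=SVRParams)
    bands: BandSpec = field(default_factory=lambda: BandSpec())
    n_subjects: int = 8
    fs: float = DEFAULT_FS
    master_seed: int = 0
    run_timefreq: bool = False

    def validate(self) -> None:
        self.behavior.validate()
        self.signal.validate()
        self.filter.validate(self.fs)
        self.window.validate()
        self.bands.validate(self.fs)
        if self.n_subjects < 2:
            raise ValueError("group analyses require n_subjects >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        import json
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a nested plain dict (e.g. parsed YAML)."""
        from .design_sim import VigilanceProcess
        d = dict(d or {})
        kwargs = {}
        builders = {"behavior": BehaviorConfig, "signal": SignalConfig,
                    "filter": FilterSpec, "glm": GLMParams,
                    "window": WindowSpec, "svr": SVRParams, "bands": BandSpec}
        for key, klass in builders.items():
            if key in d:
                sub = dict(d.pop(key))
                if key == "behavior" and "vigilance" in sub:
                    sub["vigilance"] = VigilanceProcess(**sub["vigilance"])
                kwargs[key] = klass(**sub)
        for key in ("n_subjects", "fs", "master_seed", "run_timefreq"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)


def subject_rng(master_seed: int, subject: int) -> np.random.Generator:
    """Generator for one subject, independent of how many subjects exist."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, subject)))


@dataclass
class SubjectData:
    """One simulated subject: behavior, geometry, raw optical recordings."""

    subject: int
    trials: pd.DataFrame            # onsets on the session clock
    trials_rec: pd.DataFrame        # onsets on each run's recording clock
    channels: pd.DataFrame
    attenuation: dict               # run_id -> (Recording@850nm, Recording@760nm)
    truth: pd.DataFrame             # per-trial ground-truth response amplitudes


def simulate_subject(cfg: PipelineConfig, subject: int,
                     pre_time: float = 6.0) -> SubjectData:
    """Simulate one subject through to raw two-wavelength attenuation."""
    rng = subject_rng(cfg.master_seed, subject)
    try:
        trials = design_sim.simulate_behavior(cfg.behavior, rng)
        channels = make_channel_table()
        chromo, truth = signal_sim.simulate_chromophores(
            trials, channels, cfg.signal, rng, fs=cfg.fs, pre_time=pre_time)
        attenuation = {}
        for rid, (hbo, hbr) in chromo.items():
            attenuation[rid] = signal_sim.forward_beer_lambert(
                hbo, hbr, channels, EXTINCTION_DEFAULT, DPF_DEFAULT)
        trials_rec = signal_sim.shift_onsets_to_recording(trials, pre_time)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"[simulate] subject {subject}: {e}") from e
    return SubjectData(subject, trials, trials_rec, channels, attenuation, truth)


def preprocess_subject(data: SubjectData, spec: FilterSpec):
    """Preprocess raw attenuation for one subject.

    Returns ``(chromo, chromo_norm)``: run_id -> (HbO, HbR) recordings,
    un-normalized (for the FIR GLM, which models drift itself) and
    drift-corrected + z-normalized (for the decoding analyses).
    """
    chromo, chromo_norm = {}, {}
    try:
        for rid, (a850, a760) in data.attenuation.items():
            hbo, hbr = preprocess.preprocess_run(
                a850, a760, data.channels, spec, normalize=False)
            chromo[rid] = (hbo, hbr)
            chromo_norm[rid] = (preprocess.detrend_znorm(hbo),
                                preprocess.detrend_znorm(hbr))
    except Exception as e:
        raise PipelineError(f"[preprocess] subject {data.subject}: {e}") from e
    return chromo, chromo_norm


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every analysis stage for ``cfg.n_subjects`` simulated subjects.

    Returns a bundle with per-subject GLM results, group beta statistics,
    the sliding-window decoding result, optionally the band x window map,
    and a manifest (config hash, seed, stage timings).
    """
    cfg.validate()
    manifest = {"config_hash": cfg.config_hash(),
                "master_seed": cfg.master_seed, "timings_s": {}}
    t0 = time.time()
    subjects, glm_results, fold_rs = [], [], []
    for s in range(cfg.n_subjects):
        data = simulate_subject(cfg, s)
        chromo, chromo_norm = preprocess_subject(data, cfg.filter)
        try:
            glm_results.append(fir_glm.fit_subject_glm(
                chromo, data.trials_rec, cfg.fs, cfg.glm.n_bins,
                cfg.glm.stride, cfg.glm.drift_period))
        except Exception as e:
            raise PipelineError(f"[glm] subject {s}: {e}") from e
        try:
            fold_rs.append(decoding.decode_subject(
                chromo_norm, data.trials_rec, cfg.window, cfg.svr))
        except Exception as e:
            raise PipelineError(f"[decode] subject {s}: {e}") from e
        subjects.append((chromo_norm, data.trials_rec))
        logger.info("subject %d/%d analyzed", s + 1, cfg.n_subjects)
    manifest["timings_s"]["per_subject_stages"] = round(time.time() - t0, 2)

    try:
        group_glm = {}
        for chromo_name in ("HbO", "HbR"):
            betas = np.stack([g[chromo_name].betas for g in glm_results])
            t, p = fir_glm.group_stats(betas)
            group_glm[chromo_name] = {"betas": betas, "t": t, "p": p,
                                      "labels": glm_results[0][chromo_name].labels,
                                      "bin_times": glm_results[0][chromo_name].bin_times}
        decoding_result = decoding.group_accuracy(np.asarray(fold_rs), cfg.window)
    except Exception as e:
        raise PipelineError(f"[group] {e}") from e

    band_map = None
    if cfg.run_timefreq:
        t1 = time.time()
        try:
            band_map = timefreq.band_decode(subjects, cfg.bands, cfg.window,
                                            cfg.svr)
        except Exception as e:
            raise PipelineError(f"[tfdecode] {e}") from e
        manifest["timings_s"]["timefreq"] = round(time.time() - t1, 2)

    manifest["timings_s"]["total"] = round(time.time() - t0, 2)
    return {"glm": glm_results, "group_glm": group_glm,
            "decoding": decoding_result, "band_map": band_map,
            "manifest": manifest}
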