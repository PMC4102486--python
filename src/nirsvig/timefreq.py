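"""Time-frequency decoding: wavelet band envelopes + per-band sliding-window SVR.

The preprocessed chromophore series are decomposed with a complex Morlet
continuous wavelet transform into frequency bands spanning 0.001-0.25 Hz
(250 linearly spaced bands by default).  Within each band, the amplitude
envelope (modulus of the complex coefficient) replaces the raw signal; the
sliding-window decoding of the space-time analysis is repeated per band,
except that features are the window-averaged envelope per channel (88
features) rather than the full space-time pattern.  The result is a
band x window map of group decoding accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .decoding import (SVRParams, WindowSpec, decode_subject,
                       group_accuracy, window_center_times)
from .signal_sim import Recording

logger = logging.getLogger("nirsvig.timefreq")


@dataclass
class BandSpec:
    """Frequency-band layout for the wavelet filter bank."""

    f_min: float = 0.001
    f_max: float = 0.25
    n_bands: int = 250
    spacing: str = "linear"
    wavelet: str = "cmor1.5-1.0"   # complex Morlet: bandwidth 1.5, center 1.0

    def validate(self, fs: float) -> None:
        if not (0.0 < self.f_min < self.f_max):
            raise ValueError("require 0 < f_min < f_max")
        if self.f_max > fs / 2.0:
            raise ValueError(
                f"f_max {self.f_max} Hz above Nyquist {fs / 2.0} Hz")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.spacing not in ("linear", "logarithmic"):
            raise ValueError("spacing must be 'linear' or 'logarithmic'")

    def centers(self) -> np.ndarray:
        if self.spacing == "linear":
            return np.linspace(self.f_min, self.f_max, self.n_bands)
        return np.geomspace(self.f_min, self.f_max, self.n_bands)

    def scales(self, fs: float) -> np.ndarray:
        fc = pywt.central_frequency(self.wavelet)
        return fc * fs / self.centers()


@dataclass
class BandMap:
    band_centers: np.ndarray        # Hz
    window_times: np.ndarray        # s relative to onset
    mean_z: np.ndarray              # bands x windows, group-mean Fisher-Z
    group_t: np.ndarray
    group_p: np.ndarray
    unreliable_bands: np.ndarray    # centers below 1/run-length
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_z,
                          index=np.round(self.band_centers, 6),
                          columns=np.round(self.window_times, 3))
        df.index.name = "band_hz"
        return df


def wavelet_decompose(rec: Recording, bands: BandSpec) -> np.ndarray:
    """Band x channel x sample amplitude-envelope array.

    The modulus of the complex Morlet coefficient at each band's scale,
    evaluated on the original sampling grid.
    """
    bands.validate(rec.fs)
    coef, _ = pywt.cwt(rec.data, bands.scales(rec.fs), bands.wavelet,
                       sampling_period=1.0 / rec.fs, axis=-1, method="fft")
    return np.abs(coef)


def _chunk_envelopes(recordings: dict, scales: np.ndarray, wavelet: str) -> list:
    """Per-band envelope recordings for a chunk of scales (one cwt per run)."""
    out = [dict() for _ in scales]
    for rid, (hbo, hbr) in recordings.items():
        pair = []
        for rec in (hbo, hbr):
            coef, _ = pywt.cwt(rec.data, scales, wavelet,
                               sampling_period=1.0 / rec.fs, axis=-1,
                               method="fft")
            pair.append(np.abs(coef))
        for b in range(len(scales)):
            out[b][rid] = (
                hbo.copy_with(pair[0][b], signal_kind="HbO:env"),
                hbr.copy_with(pair[1][b], signal_kind="HbR:env"))
    return out


def band_decode(subjects: list, bands: BandSpec,
                window_spec: WindowSpec | None = None,
                params: SVRParams | None = None) -> BandMap:
    """Per-band sliding-window group decoding.

    ``subjects`` is a list of ``(recordings, trials)`` pairs as consumed by
    :func:`nirsvig.decoding.decode_subject` (preprocessed recordings, trial
    onsets on the recording clock).  For each band the recordings are
    replaced by their band envelope and decoded with window-mean features;
    cross-validation, Fisher-Z aggregation and group inference are identical
    to the broadband space-time analysis.

    Bands slower than one cycle per run are kept but flagged as unreliable
    in the output (their envelopes are edge-dominated).
    """
    window_spec = window_spec or WindowSpec()
    params = params or SVRParams()
    if not subjects:
        raise ValueError("no subjects given")
    fs = next(iter(subjects[0][0].values()))[0].fs
    bands.validate(fs)
    centers = bands.centers()
    scales = bands.scales(fs)
    run_len_s = min(
        rec[0].n_samples / fs
        for recordings, _ in subjects for rec in recordings.values())
    unreliable = centers[centers < 1.0 / run_len_s]

    n_windows = len(window_center_times(window_spec))
    mean_z = np.empty((bands.n_bands, n_windows))
    group_t = np.empty_like(mean_z)
    group_p = np.empty_like(mean_z)
    # chunk the filter bank so each run's cwt covers many scales at once
    # while the envelope arrays stay comfortably in memory
    n_ch = next(iter(subjects[0][0].values()))[0].n_channels
    n_samp = max(rec[0].n_samples
                 for recordings, _ in subjects for rec in recordings.values())
    n_runs = max(len(recordings) for recordings, _ in subjects)
    chunk = max(1, int(2.5e8 / (16 * n_ch * n_samp * n_runs)))
    for c0 in range(0, bands.n_bands, chunk):
        sl = slice(c0, min(c0 + chunk, bands.n_bands))
        per_subject_envs = [
            _chunk_envelopes(recordings, scales[sl], bands.wavelet)
            for recordings, _ in subjects]
        for j in range(sl.stop - sl.start):
            b = c0 + j
            per_subject = [
                decode_subject(per_subject_envs[s][j], subjects[s][1],
                               window_spec, params, reduce="mean")
                for s in range(len(subjects))]
            res = group_accuracy(np.asarray(per_subject), window_spec)
            mean_z[b] = res.per_subject_z.mean(axis=0)
            group_t[b] = res.group_t
            group_p[b] = res.group_p
            logger.info("band %d/%d (%.4f Hz) done", b + 1, bands.n_bands,
                        centers[b])
    return BandMap(band_centers=centers,
                   window_times=window_center_times(window_spec),
                   mean_z=mean_z, group_t=group_t, group_p=group_p,
                   unreliable_bands=unreliable,
                   meta={"n_subjects": len(subjects),
                         "wavelet": bands.wavelet,
                         "spacing": bands.spacing})
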