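"""Preprocessing: low-pass filtering, Beer-Lambert inversion, drift/z-norm.

Order contract: the Butterworth low-pass applies to raw attenuation, the
modified Beer-Lambert inversion converts filtered attenuation to HbO/HbR
concentration changes, and linear drift correction + z-normalization apply
per run to the chromophore series before decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .signal_sim import (Recording, EXTINCTION_DEFAULT, DPF_DEFAULT,
                         _check_extinction)


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification.

    ``phase="zero"`` applies the filter forward and backward (no phase
    distortion of the hemodynamic peak; magnitude response squared, i.e.
    attenuation doubled in dB).  ``phase="causal"`` is a single forward pass
    with steady-state initial conditions.
    """

    cutoff: float = 0.25
    order: int = 3
    kind: str = "lowpass"
    phase: str = "zero"

    def validate(self, fs: float) -> None:
        if not (0.0 < self.cutoff < fs / 2.0):
            raise ValueError(
                f"cutoff {self.cutoff} Hz must lie in (0, Nyquist={fs / 2.0} Hz)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.phase not in ("zero", "causal"):
            raise ValueError("phase must be 'zero' or 'causal'")

    def to_dict(self) -> dict:
        return asdict(self)


def butterworth_gain(freq, cutoff: float, order: int, zero_phase: bool = False,
                     fs: float | None = None):
    """Closed-form Butterworth magnitude response |H(f)|.

    Analog prototype: ``|H| = (1 + (f/fc)^(2n))^(-1/2)``.  With ``fs`` given,
    the frequency axis is pre-warped (``tan(pi f / fs)``), which is the exact
    magnitude response of the bilinear-transform digital filter that
    :func:`lowpass` applies.  Squared for zero-phase forward-backward
    filtering.
    """
    f = np.asarray(freq, dtype=float)
    if fs is not None:
        f = np.tan(np.pi * f / fs)
        cutoff = np.tan(np.pi * cutoff / fs)
    g = 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))
    return g ** 2 if zero_phase else g


def lowpass(rec: Recording, spec: FilterSpec) -> Recording:
    """Low-pass filter every channel; DC gain is exactly 1."""
    spec.validate(rec.fs)
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=rec.fs,
                     output="sos")
    x = rec.data
    if spec.phase == "zero":
        y = sps.sosfiltfilt(sos, x, axis=1)
    else:
        # steady-state initialization per channel suppresses the start-up
        # transient for signals with nonzero baseline
        zi = sps.sosfilt_zi(sos)
        y = np.empty_like(x)
        for c in range(x.shape[0]):
            y[c], _ = sps.sosfilt(sos, x[c], zi=zi * x[c, 0])
    out = rec.copy_with(y)
    out.meta.update({"lowpass_cutoff_hz": spec.cutoff,
                     "lowpass_order": spec.order,
                     "lowpass_phase": spec.phase,
                     "edge_seconds_flagged": 5.0})
    return out


def mbll_invert(a850: Recording, a760: Recording, channels,
                extinction: np.ndarray = EXTINCTION_DEFAULT,
                dpf=DPF_DEFAULT) -> tuple[Recording, Recording]:
    """Invert the modified Beer-Lambert law: attenuation -> (HbO, HbR).

    Solves, per channel and sample, the 2x2 linear system
    ``dA(lambda) = eps(lambda, :) . dC * distance * DPF(lambda)`` for the
    chromophore concentration changes ``dC = (dHbO, dHbR)``.
    """
    E = _check_extinction(extinction)
    if a850.data.shape != a760.data.shape:
        raise ValueError("wavelength recordings are not aligned")
    if len(channels) != a850.n_channels:
        raise ValueError(
            f"channel table has {len(channels)} rows but recording has "
            f"{a850.n_channels} channels"
        )
    Einv = np.linalg.inv(E)
    dist = channels["distance_cm"].to_numpy()
    # normalise out pathlength first: dA_norm(lambda) = eps . dC
    n850 = a850.data / (dist[:, None] * dpf[0])
    n760 = a760.data / (dist[:, None] * dpf[1])
    hbo = Einv[0, 0] * n850 + Einv[0, 1] * n760
    hbr = Einv[1, 0] * n850 + Einv[1, 1] * n760
    meta = dict(a850.meta)
    meta.update({"extinction": np.asarray(extinction).tolist(), "dpf": list(dpf)})
    rec_hbo = Recording(hbo, a850.fs, a850.run_id, "HbO", units="mM*cm",
                        channel_ids=list(a850.channel_ids), meta=meta)
    rec_hbr = Recording(hbr, a850.fs, a850.run_id, "HbR", units="mM*cm",
                        channel_ids=list(a850.channel_ids), meta=dict(meta))
    return rec_hbo, rec_hbr


def detrend_znorm(rec: Recording) -> Recording:
    """Per-channel linear drift removal and z-normalization (one run).

    Subtracts the least-squares line then divides by the residual standard
    deviation, so every channel leaves with mean ~0 and sd 1.  A channel
    that is constant (or a pure line) has nothing left to normalise and is
    reported as an error.
    """
    if rec.n_samples < 3:
        raise ValueError("need at least 3 samples per channel to detrend")
    y = sps.detrend(rec.data, axis=1, type="linear")
    sd = y.std(axis=1)
    scale = np.sqrt((rec.data ** 2).mean(axis=1))
    bad = np.where(sd <= 1e-10 * np.maximum(scale, 1e-300))[0]
    if bad.size:
        names = [rec.channel_ids[i] for i in bad]
        raise ValueError(f"zero variance after detrend in channel(s): {names}")
    out = rec.copy_with(y / sd[:, None])
    out.meta["detrended_znormed"] = True
    return out


def preprocess_run(a850: Recording, a760: Recording, channels,
                   spec: FilterSpec | None = None,
                   extinction: np.ndarray = EXTINCTION_DEFAULT,
                   dpf=DPF_DEFAULT,
                   normalize: bool = True) -> tuple[Recording, Recording]:
    """Full preprocessing of one run in the contract order.

    lowpass(attenuation) -> Beer-Lambert inversion -> optional per-run
    drift correction + z-normalization (used by the decoding analyses; the
    FIR-GLM consumes un-normalized chromophore series and models drift with
    its cosine basis).
    """
    spec = spec or FilterSpec()
    f850 = lowpass(a850, spec)
    f760 = lowpass(a760, spec)
    hbo, hbr = mbll_invert(f850, f760, channels, extinction, dpf)
    if normalize:
        hbo = detrend_znorm(hbo)
        hbr = detrend_znorm(hbr)
    return hbo, hbr
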