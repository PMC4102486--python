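"""Readers and writers: delimited-text and HDF5 containers, events, configs.

Two interchangeable on-disk forms for recordings:

* plain UTF-8 tab-separated text, one file per run per signal kind, with
  ``# key: value`` header lines carrying metadata (fs, run, units,
  provenance) and a channel-id header row — the canonical deliverable form;
* an HDF5 container in the spirit of SNIRF (one group per run holding the
  data matrix, sampling rate, signal labels and the channel table).

Trial tables are BIDS-events-like TSV.  Configs are YAML and are echoed
into output headers for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .signal_sim import Recording


class FormatError(ValueError):
    """Malformed or incomplete on-disk recording."""


EVENT_COLUMNS = ["onset", "duration", "run", "condition", "attention",
                 "correct", "rt_ms", "rt_corrected_ms", "vigilance_ms",
                 "trial_index"]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as a BIDS-events-like TSV."""
    out = pd.DataFrame({
        "onset": trials["onset"],
        "duration": trials["duration"],
        "run": trials["run_id"],
        "condition": trials["condition"],
        "attention": trials["attention"],
        "correct": trials["correct"].astype(int),
        "rt_ms": trials["rt"],
        "rt_corrected_ms": trials["rt_corrected"],
        "vigilance_ms": trials.get("vigilance", np.nan),
        "trial_index": trials["trial_index"],
    })
    out.to_csv(path, sep="\t", index=False, na_rep="n/a",
               float_format="%.17g")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = set(EVENT_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    return pd.DataFrame({
        "trial_index": df.get("trial_index", pd.RangeIndex(len(df))),
        "run_id": df["run"].astype(int),
        "onset": df["onset"].astype(float),
        "duration": df["duration"].astype(float),
        "condition": df["condition"],
        "attention": df["attention"],
        "correct": df["correct"].astype(bool),
        "rt": df["rt_ms"].astype(float),
        "rt_corrected": df["rt_corrected_ms"].astype(float),
        "vigilance": df.get("vigilance_ms", np.nan),
    })


# ---------------------------------------------------------------- text format

def write_recording_text(rec: Recording, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nirsvig-recording v1\n")
        fh.write(f"# fs_hz: {rec.fs!r}\n")
        fh.write(f"# run_id: {rec.run_id}\n")
        fh.write(f"# signal_kind: {rec.signal_kind}\n")
        fh.write(f"# units: {rec.units}\n")
        if rec.meta:
            fh.write(f"# meta: {json.dumps(rec.meta, sort_keys=True)}\n")
        fh.write("\t".join(str(c) for c in rec.channel_ids) + "\n")
        np.savetxt(fh, rec.data.T, delimiter="\t", fmt="%.17g")


def read_recording_text(path) -> Recording:
    path = Path(path)
    header: dict = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        if not line:
            raise FormatError(f"{path}: empty recording file")
        channel_ids = line.rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if "fs_hz" not in header:
        raise FormatError(f"{path}: missing required header field 'fs_hz'")
    meta = json.loads(header["meta"]) if "meta" in header else {}
    return Recording(data.T, fs=float(header["fs_hz"]),
                     run_id=int(header.get("run_id", 0)),
                     signal_kind=header.get("signal_kind", ""),
                     units=header.get("units", ""),
                     channel_ids=channel_ids, meta=meta)


# ---------------------------------------------------------------- HDF5 format

def write_recordings_hdf5(recordings: dict, path,
                          channels: pd.DataFrame | None = None) -> None:
    """SNIRF-style container: one group per run and signal kind."""
    with h5py.File(path, "w") as h5:
        for rid, recs in recordings.items():
            if isinstance(recs, Recording):
                recs = (recs,)
            for rec in recs:
                g = h5.create_group(f"run{rid}/{rec.signal_kind}")
                g.create_dataset("data", data=rec.data)
                g.attrs["fs_hz"] = rec.fs
                g.attrs["run_id"] = rec.run_id
                g.attrs["units"] = rec.units
                g.attrs["meta"] = json.dumps(rec.meta, sort_keys=True)
                g.create_dataset("channel_ids",
                                 data=np.array(rec.channel_ids, dtype="S"))
        if channels is not None:
            g = h5.create_group("channel_table")
            for col in channels.columns:
                vals = channels[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)


def read_recordings_hdf5(path) -> dict:
    """Inverse of :func:`write_recordings_hdf5` (recordings part)."""
    out: dict = {}
    with h5py.File(path, "r") as h5:
        for run_key in sorted(k for k in h5 if k.startswith("run")):
            rid = int(run_key[3:])
            out[rid] = {}
            for kind in h5[run_key]:
                g = h5[run_key][kind]
                if "fs_hz" not in g.attrs:
                    raise FormatError(f"{path}:{run_key}/{kind}: missing fs_hz")
                out[rid][kind] = Recording(
                    g["data"][()], fs=float(g.attrs["fs_hz"]),
                    run_id=int(g.attrs.get("run_id", rid)),
                    signal_kind=kind, units=str(g.attrs.get("units", "")),
                    channel_ids=[c.decode() for c in g["channel_ids"][()]],
                    meta=json.loads(g.attrs.get("meta", "{}")))
    return out


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".snirf"):
        write_recordings_hdf5({rec.run_id: rec}, path)
    else:
        write_recording_text(rec, path)


def read_recording(path) -> Recording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".snirf"):
        runs = read_recordings_hdf5(path)
        rid = sorted(runs)[0]
        kind = sorted(runs[rid])[0]
        return runs[rid][kind]
    return read_recording_text(path)


def validate_recording(rec: Recording) -> pd.DataFrame:
    """Report non-finite samples: one row per offending (channel, sample)."""
    ch, idx = np.where(~np.isfinite(rec.data))
    return pd.DataFrame({"channel": [rec.channel_ids[c] for c in ch],
                         "channel_index": ch, "sample_index": idx})


def write_channel_table(channels: pd.DataFrame, path) -> None:
    channels.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_channel_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"channel_id", "source_id", "detector_id", "distance_cm"} \
        - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing channel columns {sorted(missing)}")
    return df


def write_config(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
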