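"""Readers and writers for recordings, events and montages.

Recordings travel either as a SNIRF-style HDF5 container (two-wavelength
intensity time series plus stimulus table) or as a plain wide CSV (first
column time in seconds, then one column per channel per wavelength, headers
``chNN_760`` / ``chNN_850``).  Events are a TSV with one row per trial.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage
from .synthetic import DesignSchedule, SyntheticRecording, TrialSpec

__all__ = [
    "RawRecording", "write_recording_snirf", "read_recording_snirf",
    "write_recording_csv", "read_recording_csv", "write_events_tsv",
    "read_events_tsv", "sha256_of", "read_recording",
]


@dataclass
class RawRecording:
    """Two-wavelength intensity matrices as read from disk."""

    raw_intensity: dict[int, np.ndarray]   # nm -> channel x time
    time: np.ndarray
    sampling_rate: float
    channel_ids: list[int]


def write_recording_snirf(rec: SyntheticRecording, path: str | Path) -> Path:
    """SNIRF-style HDF5: /nirs/data1 holds the stacked intensity series
    with one measurementList entry per channel-wavelength pair."""
    path = Path(path)
    wavelengths = sorted(rec.raw_intensity)
    nch = rec.n_channels
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        data = nirs.create_group("data1")
        stacked = np.vstack([rec.raw_intensity[wl] for wl in wavelengths]).T
        data.create_dataset("dataTimeSeries", data=stacked)
        data.create_dataset("time", data=rec.time)
        for j, wl in enumerate(wavelengths):
            for ch in range(nch):
                ml = data.create_group(f"measurementList{j * nch + ch + 1}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=j + 1)
        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="nback_level")
        stim.create_dataset("data", data=np.array(
            [[t.sign_onset, t.duration, t.nback_level]
             for t in rec.design.trials]))
    return path


def read_recording_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        try:
            wavelengths = [int(w) for w in f["nirs/probe/wavelengths"][()]]
            stacked = f["nirs/data1/dataTimeSeries"][()]
            time = f["nirs/data1/time"][()]
        except KeyError as exc:
            raise ValueError(f"malformed SNIRF container {path}: "
                             f"missing {exc.args[0]}") from None
    nch = stacked.shape[1] // len(wavelengths)
    raw = {wl: stacked[:, i * nch:(i + 1) * nch].T
           for i, wl in enumerate(wavelengths)}
    fs = 1.0 / np.median(np.diff(time))
    return RawRecording(raw, time, float(fs), list(range(1, nch + 1)))


def write_recording_csv(rec: SyntheticRecording, path: str | Path) -> Path:
    path = Path(path)
    cols = {"time_s": rec.time}
    for wl in sorted(rec.raw_intensity):
        for ch in range(rec.n_channels):
            cols[f"ch{ch + 1:02d}_{wl}"] = rec.raw_intensity[wl][ch]
    # default float repr round-trips exactly, keeping CSV and HDF5 paths
    # numerically identical downstream
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


_CH_RE = re.compile(r"^ch(\d+)_(\d+)$")


def read_recording_csv(path: str | Path) -> RawRecording:
    # round_trip parsing keeps the CSV path bit-identical to HDF5
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    by_wl: dict[int, dict[int, np.ndarray]] = {}
    for col in df.columns:
        m = _CH_RE.match(col)
        if m:
            ch, wl = int(m.group(1)), int(m.group(2))
            by_wl.setdefault(wl, {})[ch] = df[col].to_numpy(float)
    if not by_wl:
        raise ValueError(f"{path}: no channel columns (chNN_wavelength)")
    channel_ids = sorted(next(iter(by_wl.values())))
    for wl, chans in by_wl.items():
        missing = set(channel_ids) - set(chans)
        if missing:
            raise ValueError(
                f"{path}: missing column ch{min(missing):02d}_{wl}")
    raw = {wl: np.vstack([chans[c] for c in channel_ids])
           for wl, chans in by_wl.items()}
    time = df["time_s"].to_numpy(float)
    fs = 1.0 / np.median(np.diff(time))
    return RawRecording(raw, time, float(fs), channel_ids)


def read_recording(path: str | Path) -> RawRecording:
    """Dispatch on container type (HDF5/SNIRF vs CSV)."""
    path = Path(path)
    if path.suffix.lower() in {".snirf", ".h5", ".hdf5"}:
        return read_recording_snirf(path)
    return read_recording_csv(path)


EVENT_COLUMNS = ["onset_s", "duration_s", "nback_level", "sign_speed_kmh",
                 "target_speed_kmh", "correct", "block_id", "trial_index"]


def write_events_tsv(design: DesignSchedule, path: str | Path) -> Path:
    path = Path(path)
    df = design.to_frame().rename(columns={"onset_s": "onset_s"})
    df = df[["trial_index", "block_id", "nback_level", "onset_s",
             "duration_s", "sign_speed_kmh", "target_speed_kmh", "correct"]]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> DesignSchedule:
    df = pd.read_csv(path, sep="\t")
    trials = [
        TrialSpec(int(r.trial_index), int(r.block_id), int(r.nback_level),
                  float(r.onset_s), float(r.duration_s),
                  int(r.sign_speed_kmh), int(r.target_speed_kmh),
                  bool(r.correct))
        for r in df.itertuples()
    ]
    order = list(df.drop_duplicates("block_id")["nback_level"].astype(int))
    return DesignSchedule(trials, order, seed=-1)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
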