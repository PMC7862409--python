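"""File I/O for signals, beats, and reports.

Baseband records travel as 4-channel WAV (channel order B3, B4, B5, B6,
float samples) or CSV with columns ``t, b3, b4, b5, b6``; displacement as
CSV ``t, x`` or single-channel WAV; beat lists as single-column CSV in
seconds; configs as YAML.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .errors import InvalidInputError
from .types import BasebandRecord, BeatList, DisplacementSignal, WAVELENGTH_24GHZ

_CHANNELS = ("b3", "b4", "b5", "b6")


def read_baseband(path: str | Path, fs: float | None = None) -> BasebandRecord:
    """Read a 4-channel baseband record from WAV or CSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if data.ndim != 2 or data.shape[1] != 4:
            raise InvalidInputError(
                f"{path} must have 4 channels, got shape {data.shape}")
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / np.iinfo(data.dtype).max
        cols = {c: data[:, k].astype(float) for k, c in enumerate(_CHANNELS)}
        return BasebandRecord(fs=float(rate), **cols)
    df = pd.read_csv(path)
    missing = [c for c in _CHANNELS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path} missing columns {missing}")
    if fs is None:
        if "t" not in df.columns or len(df) < 2:
            raise InvalidInputError("CSV needs a 't' column or an explicit fs")
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    return BasebandRecord(fs=fs, **{c: df[c].to_numpy(float) for c in _CHANNELS})


def write_baseband(path: str | Path, rec: BasebandRecord) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        data = np.column_stack([rec.b3, rec.b4, rec.b5, rec.b6]).astype(np.float32)
        wavfile.write(path, int(round(rec.fs)), data)
        return
    t = np.arange(rec.n_samples) / rec.fs
    pd.DataFrame({"t": t, "b3": rec.b3, "b4": rec.b4,
                  "b5": rec.b5, "b6": rec.b6}).to_csv(path, index=False)


def read_displacement(path: str | Path, fs: float | None = None,
                      wavelength: float = WAVELENGTH_24GHZ) -> DisplacementSignal:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        return DisplacementSignal(x=np.asarray(data, float).ravel(),
                                  fs=float(rate), wavelength=wavelength)
    df = pd.read_csv(path)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    return DisplacementSignal(x=df["x"].to_numpy(float), fs=fs,
                              wavelength=wavelength)


def write_displacement(path: str | Path, disp: DisplacementSignal) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(disp.fs)), disp.x.astype(np.float32))
        return
    pd.DataFrame({"t": disp.t, "x": disp.x}).to_csv(path, index=False)


def read_beats(path: str | Path) -> BeatList:
    """Single-column CSV of beat times in seconds (header optional)."""
    try:
        vals = pd.read_csv(path, header=None, comment="#")[0].to_numpy()
        vals = vals.astype(float)
    except (ValueError, TypeError):
        vals = pd.read_csv(path).iloc[:, 0].to_numpy(float)
    return BeatList(times=vals)


def write_beats(path: str | Path, beats: BeatList) -> None:
    pd.DataFrame({"beat_time_s": beats.times}).to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
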