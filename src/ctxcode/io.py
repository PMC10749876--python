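"""Interchange formats: HDF5 recordings, JSON sequences, tidy CSV tables.

Recording layout (HDF5): ``/counts`` (neurons x trials x time, 20 Hz),
``/fine_counts`` (100 Hz), ``/pupil`` (trials x time), ``/tables/trials``
and ``/tables/neurons`` (column datasets), and the sequence set as a JSON
attribute.  CSV outputs are rounded to 6 significant digits so that
repeated runs are byte-identical across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .stimdesign import SequenceSet
from .synthgen import PopulationRecording

__all__ = ["save_recording", "load_recording", "write_csv"]


def _write_table(grp: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object or data.dtype.kind == "U":
            data = np.array([str(x) for x in data], dtype="S")
        grp.create_dataset(col, data=data)


def _read_table(grp: h5py.Group) -> pd.DataFrame:
    out = {}
    for col in grp:
        data = grp[col][...]
        if data.dtype.kind == "S":
            data = data.astype(str)
        out[col] = data
    return pd.DataFrame(out)


def save_recording(rec: PopulationRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=rec.counts)
        f.create_dataset("fine_counts", data=rec.fine_counts)
        f.create_dataset("pupil", data=rec.pupil)
        _write_table(f.create_group("tables/trials"), rec.trial_table)
        _write_table(f.create_group("tables/neurons"), rec.neuron_table)
        f.attrs["sequences_json"] = rec.sequences.to_json()
        f.attrs["bin_dt"] = rec.bin_dt
        f.attrs["fine_dt"] = rec.fine_dt


def load_recording(path: str | Path) -> PopulationRecording:
    with h5py.File(path, "r") as f:
        return PopulationRecording(
            counts=f["counts"][...],
            fine_counts=f["fine_counts"][...],
            pupil=f["pupil"][...],
            trial_table=_read_table(f["tables/trials"]),
            neuron_table=_read_table(f["tables/neurons"]),
            sequences=SequenceSet.from_json(f.attrs["sequences_json"]),
            bin_dt=float(f.attrs["bin_dt"]),
            fine_dt=float(f.attrs["fine_dt"]),
        )


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="-"))


def write_csv(df: pd.DataFrame, path: str | Path, sig: int = 6) -> None:
    """Write a tidy CSV with floats rounded to ``sig`` significant digits."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: _round_sig(v, sig))
    out.to_csv(path, index=False)
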