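"""Readers and writers for waveform records and processed datasets.

Formats:

* **HDF5 record container** — one group per record with datasets ``ppg``
  and ``abp`` and attributes ``fs`` plus a JSON echo of the generator
  config and per-beat ground truth where available.
* **Two-column CSV** — ``ppg,abp`` columns, sampling rate in a
  ``# fs=...`` comment line; the portable plain-text form of one record.
* **MAT v7.3 cell layouts** — HDF5-based containers in which a top-level
  cell array holds one channels-by-samples matrix per record, PPG in the
  first row and ABP in the second (the layout used by the public UCI
  cuff-less BP records).
* **Processed dataset HDF5** — datasets ``inputs`` (N x 3 x 375),
  ``labels`` (N x 2), ``record_id`` and ``start_index`` (N), with the
  screening summary stored as a JSON attribute.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .preprocess import ModelInput
from .synth import WaveformRecord

__all__ = [
    "write_records_hdf5",
    "read_records_hdf5",
    "write_record_csv",
    "read_record_csv",
    "read_mat_records",
    "write_processed_hdf5",
    "read_processed_hdf5",
    "write_predictions_csv",
    "read_predictions_csv",
]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_records_hdf5(records: Sequence[WaveformRecord], path) -> None:
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(records):
            g = f.create_group(f"record_{i:05d}")
            g.create_dataset("ppg", data=rec.ppg)
            g.create_dataset("abp", data=rec.abp)
            g.attrs["fs"] = rec.fs
            g.attrs["meta"] = json.dumps(_json_safe(rec.meta))


def read_records_hdf5(path) -> list[WaveformRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            meta = json.loads(g.attrs.get("meta", "{}"))
            records.append(
                WaveformRecord(
                    ppg=g["ppg"][...], abp=g["abp"][...],
                    fs=float(g.attrs["fs"]), meta=meta,
                )
            )
    return records


def write_record_csv(record: WaveformRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs}\n")
        fh.write("ppg,abp\n")
        for p, a in zip(record.ppg, record.abp):
            fh.write(f"{p:.8g},{a:.8g}\n")


def read_record_csv(path, fs: float | None = None) -> WaveformRecord:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("# fs="):
        fs = float(first.split("=", 1)[1])
    elif fs is None:
        raise ValueError(f"{path}: no '# fs=' header and no fs argument given")
    df = pd.read_csv(path, comment="#")
    return WaveformRecord(ppg=df["ppg"].to_numpy(), abp=df["abp"].to_numpy(), fs=fs,
                          meta={"source": str(path)})


def read_mat_records(path, fs: float = 125.0, ppg_row: int = 0,
                     abp_row: int = 1) -> list[WaveformRecord]:
    """Read a MAT v7.3 (HDF5-based) cell-array container of records.

    Each cell is a channels-by-samples matrix; ``ppg_row`` and ``abp_row``
    select the PPG and ABP channels.  Matrices stored samples-by-channels
    (more rows than columns) are transposed automatically.
    """
    records = []
    with h5py.File(path, "r") as f:
        # first non-internal top-level variable holds the cell array
        var = next(k for k in f.keys() if not k.startswith("#"))
        cells = f[var]
        refs = np.asarray(cells[...]).ravel()
        for i, r in enumerate(refs):
            mat = np.asarray(f[r][...]) if isinstance(r, h5py.Reference) else np.asarray(r)
            if mat.ndim != 2:
                raise ValueError(f"record {i} in {path} is not a 2-D matrix")
            if mat.shape[0] > mat.shape[1]:  # stored samples x channels
                mat = mat.T
            if mat.shape[0] <= max(ppg_row, abp_row):
                raise ValueError(
                    f"record {i} has {mat.shape[0]} channels; need rows "
                    f"{ppg_row} (PPG) and {abp_row} (ABP)"
                )
            records.append(
                WaveformRecord(
                    ppg=mat[ppg_row].astype(float),
                    abp=mat[abp_row].astype(float),
                    fs=fs,
                    meta={"source": str(path), "record_id": i},
                )
            )
    return records


def write_processed_hdf5(inputs: Sequence[ModelInput], path,
                         screening_summary: dict | None = None) -> None:
    X = np.stack([m.channels for m in inputs]).astype(np.float32)
    y = np.asarray([m.labels for m in inputs], dtype=float)
    rid = np.asarray(
        [m.record_id if m.record_id is not None else -1 for m in inputs], dtype=np.int64
    )
    start = np.asarray([m.start_index for m in inputs], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=X)
        f.create_dataset("labels", data=y)
        f.create_dataset("record_id", data=rid)
        f.create_dataset("start_index", data=start)
        if screening_summary is not None:
            f.attrs["screening"] = json.dumps(_json_safe(screening_summary))


def read_processed_hdf5(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        X = f["inputs"][...]
        y = f["labels"][...]
        rid = f["record_id"][...]
        screening = json.loads(f.attrs.get("screening", "{}"))
    return X, y, rid, screening


_PRED_COLUMNS = ["record_id", "segment_index", "sbp_ref", "dbp_ref", "sbp_pred", "dbp_pred"]


def write_predictions_csv(path, pred: np.ndarray, ref: np.ndarray,
                          record_ids=None, segment_index=None) -> None:
    n = len(pred)
    df = pd.DataFrame(
        {
            "record_id": record_ids if record_ids is not None else np.full(n, -1),
            "segment_index": segment_index if segment_index is not None else np.arange(n),
            "sbp_ref": ref[:, 0],
            "dbp_ref": ref[:, 1],
            "sbp_pred": pred[:, 0],
            "dbp_pred": pred[:, 1],
        },
        columns=_PRED_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_predictions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_PRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing prediction columns {sorted(missing)}")
    return df
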