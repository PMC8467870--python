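"""HDF5/CSV/JSON persistence for signals, segments, features, and reports.

Interchange conventions: HDF5 for signal and feature arrays, CSV for
manifests and probability/decision tables, JSON for model metadata and
evaluation reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import Segment
from .synthetic import EEGRecord

__all__ = [
    "save_records_hdf5",
    "load_records_hdf5",
    "save_segments_hdf5",
    "load_segments_hdf5",
    "save_features_hdf5",
    "load_features_hdf5",
    "segment_manifest",
    "write_probability_table",
    "read_probability_table",
    "write_json",
]


def save_records_hdf5(path: str | Path, records: list[EEGRecord]) -> None:
    with h5py.File(path, "w") as fh:
        for rec in records:
            g = fh.create_group(rec.record_id)
            g.create_dataset("samples", data=rec.samples, compression="gzip")
            g.create_dataset("labels", data=rec.labels, compression="gzip")
            g.attrs["sampling_rate"] = rec.sampling_rate


def load_records_hdf5(path: str | Path) -> list[EEGRecord]:
    records = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            records.append(
                EEGRecord(
                    samples=g["samples"][...],
                    labels=g["labels"][...],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    record_id=name,
                )
            )
    return records


def save_segments_hdf5(path: str | Path, segments: list[Segment]) -> None:
    X = np.stack([s.x for s in segments]) if segments else np.empty((0, 0))
    with h5py.File(path, "w") as fh:
        fh.create_dataset("x", data=X, compression="gzip")
        fh.create_dataset("label", data=np.array([s.label for s in segments], dtype=np.int8))
        fh.create_dataset(
            "source_record",
            data=np.array([s.source_record for s in segments], dtype=h5py.string_dtype()),
        )
        fh.create_dataset("start_offset", data=np.array([s.start_offset for s in segments]))


def load_segments_hdf5(path: str | Path) -> list[Segment]:
    with h5py.File(path, "r") as fh:
        X = fh["x"][...]
        labels = fh["label"][...]
        sources = [s.decode() for s in fh["source_record"][...]]
        offsets = fh["start_offset"][...]
    return [
        Segment(x=X[i], label=int(labels[i]), source_record=sources[i],
                start_offset=float(offsets[i]))
        for i in range(len(labels))
    ]


def save_features_hdf5(path: str | Path, *, band: np.ndarray, expert: np.ndarray,
                       labels: np.ndarray, record_ids: list[str],
                       expert_names: list[str]) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("band_matrix", data=band, compression="gzip")
        fh.create_dataset("expert", data=expert, compression="gzip")
        fh.create_dataset("label", data=np.asarray(labels, dtype=np.int8))
        fh.create_dataset(
            "record_id", data=np.array(record_ids, dtype=h5py.string_dtype())
        )
        fh["expert"].attrs["columns"] = json.dumps(expert_names)


def load_features_hdf5(path: str | Path):
    with h5py.File(path, "r") as fh:
        band = fh["band_matrix"][...]
        expert = fh["expert"][...]
        labels = fh["label"][...]
        record_ids = [s.decode() for s in fh["record_id"][...]]
        names = json.loads(fh["expert"].attrs["columns"])
    return band, expert, labels, record_ids, names


def segment_manifest(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [s.source_record for s in segments],
            "start_offset": [s.start_offset for s in segments],
            "label": [s.label for s in segments],
        }
    )


def write_probability_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_probability_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
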