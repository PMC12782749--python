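"""Recording container and on-disk formats.

Recordings are channels x samples arrays with a sampling rate, per-channel
labels and a subject id. They round-trip through an HDF5 container (one file
per subject, dataset ``data`` with attributes ``fs``/``subject_id`` and
per-channel string metadata). Channel tables and feature tables are TSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

POSITIVE_LABELS = frozenset({"SZ", "FCD", "EpiNet"})
NEGATIVE_LABELS = frozenset({"nSZ", "nonFCD", "nonEpiNet"})


def is_positive_label(label: str) -> bool:
    """Map the unified label vocabulary onto a positive-class flag.

    Training cohorts use SZ/nSZ (clinically identified seizure zone), test
    cohorts FCD/nonFCD (histopathology), synthetic cohorts EpiNet/nonEpiNet.
    The same evaluation code serves all three.
    """
    if label in POSITIVE_LABELS:
        return True
    if label in NEGATIVE_LABELS:
        return False
    if label == "unknown":
        return False
    raise ValueError(f"unrecognized channel label: {label!r}")


@dataclass
class Recording:
    """One subject's multichannel recording."""

    data: np.ndarray  # (n_channels, n_samples), float64
    fs: float  # Hz
    subject_id: str
    channel_ids: list[str]
    labels: list[str]  # per-channel, unified vocabulary
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (channels x samples)")
        q = self.data.shape[0]
        if len(self.channel_ids) != q or len(self.labels) != q:
            raise ValueError("channel metadata length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def positive_mask(self) -> np.ndarray:
        return np.array([is_positive_label(l) for l in self.labels])

    def segment(self, start_s: float, stop_s: float) -> "Recording":
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError("segment outside recording")
        return Recording(
            self.data[:, i0:i1],
            self.fs,
            self.subject_id,
            list(self.channel_ids),
            list(self.labels),
            dict(self.meta),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=self.data)
            dset.attrs["fs"] = self.fs
            dset.attrs["subject_id"] = self.subject_id
            f.create_dataset(
                "channel_ids", data=np.array(self.channel_ids, dtype="S64")
            )
            f.create_dataset("labels", data=np.array(self.labels, dtype="S32"))
            dset.attrs["meta"] = json.dumps(self.meta, default=_json_default)

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValueError(f"{path}: not a recording container")
            dset = f["data"]
            if "fs" not in dset.attrs:
                raise ValueError(f"{path}: missing sampling rate")
            return cls(
                data=dset[()],
                fs=float(dset.attrs["fs"]),
                subject_id=str(dset.attrs["subject_id"]),
                channel_ids=[s.decode() for s in f["channel_ids"][()]],
                labels=[s.decode() for s in f["labels"][()]],
                meta=json.loads(dset.attrs.get("meta", "{}")),
            )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_recording(path: str | Path) -> Recording:
    """Load a recording container, erroring on unknown formats."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return Recording.load(path)
    except OSError as exc:
        raise ValueError(f"{path}: unknown recording format") from exc


def apply_channel_table(rec: Recording, table: pd.DataFrame) -> Recording:
    """Relabel a recording from a (subject_id, channel_id, label) table.

    Channels missing from the table get label ``unknown`` with a warning.
    """
    sub = table[table["subject_id"].astype(str) == rec.subject_id]
    lookup = dict(zip(sub["channel_id"].astype(str), sub["label"].astype(str)))
    labels = []
    for ch in rec.channel_ids:
        if ch not in lookup:
            warnings.warn(f"channel {ch} missing from channel table; labelled unknown")
            labels.append("unknown")
        else:
            labels.append(lookup[ch])
    rec.labels = labels
    return rec


def write_channel_table(recs: list[Recording], path: str | Path) -> pd.DataFrame:
    rows = [
        {"subject_id": r.subject_id, "channel_id": c, "label": l}
        for r in recs
        for c, l in zip(r.channel_ids, r.labels)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_channel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "channel_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"channel table must have columns {sorted(required)}")
    if df.duplicated(["subject_id", "channel_id"]).any():
        raise ValueError("duplicate (subject, channel) keys in channel table")
    return df
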