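"""On-disk layout for labeled extremity-recording datasets.

A dataset directory holds one CSV per (recording, extremity) named
``<trial>__<extremity>.csv`` plus a ``labels.csv`` index with columns
``file, trial_id, extremity, label`` (and, for simulated data, the
generating parameters).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError
from .simulate import LabeledDataset
from .trc import ExtremityRecording, read_extremity_csv, write_extremity_csv

LABELS_FILE = "labels.csv"


def write_dataset_dir(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """Write a labeled dataset as per-extremity CSVs plus a labels index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (rec, lab) in enumerate(zip(dataset.records, dataset.labels)):
        trial = f"rec{i:05d}"
        fname = f"{trial}__{rec.extremity}.csv"
        write_extremity_csv(rec, out_dir / fname)
        row = {
            "file": fname,
            "trial_id": trial,
            "extremity": rec.extremity,
            "label": rec.label,
        }
        if i < len(dataset.configs):
            cfg = dataclasses.asdict(dataset.configs[i])
            row.update({f"param_{k}": _scalarize(v) for k, v in cfg.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / LABELS_FILE, index=False)
    return out_dir


def _scalarize(v):
    if isinstance(v, (tuple, list, np.ndarray)):
        return ";".join(f"{x:g}" for x in v)
    return v


def read_dataset_dir(in_dir: str | Path) -> tuple[list[ExtremityRecording], np.ndarray]:
    """Load a dataset directory; returns (records, integer labels)."""
    in_dir = Path(in_dir)
    index = in_dir / LABELS_FILE
    if not index.exists():
        raise DataError(f"{in_dir}: no {LABELS_FILE} index found")
    df = pd.read_csv(index)
    for col in ("file", "extremity", "label"):
        if col not in df.columns:
            raise DataError(f"{index}: missing required column {col!r}")
    records, labels = [], []
    for _, row in df.iterrows():
        rec = read_extremity_csv(
            in_dir / row["file"], extremity=row["extremity"], label=row["label"]
        )
        records.append(rec)
        labels.append(1 if row["label"] == "present" else 0)
    return records, np.asarray(labels, dtype=int)
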