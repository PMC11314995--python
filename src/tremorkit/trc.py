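"""TRC and per-extremity CSV input/output for optical motion-capture data.

Recordings are full-body marker trajectory blocks: frames as rows at a fixed
frame rate (120 Hz clinically), one (x, y, z) triplet of columns per marker,
positions in millimetres. TRC files follow the Motion Analysis tab-separated
dialect: three metadata lines, a marker-name line, an axis-label line
(X1/Y1/Z1 ...), a blank line, then ``Frame# Time`` + kinematic columns.
Trailing blank columns are tolerated. Missing samples become NaN on read and
can be linearly interpolated up to a configurable maximum gap.

Clinician annotations use a free-text vocabulary of 14 raw labels which
:func:`map_annotation` dichotomizes into present/absent: every size
qualifier ("Not much" ... "Severe", "Other") means tremor was seen, while
"Absent" and the dystonia/dyskinesia category mean it was not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError, ParseError
from .markers import DEFAULT_MARKER_MAP, EXTREMITIES, validate_marker_map

logger = logging.getLogger(__name__)

LABEL_PRESENT = "present"
LABEL_ABSENT = "absent"

#: Raw clinician label -> binary training label (closed 14-item vocabulary).
ANNOTATION_MAP: dict[str, str] = {
    "absent": LABEL_ABSENT,
    "dystonia, dyskinesia, or other abnormal posture or movement": LABEL_ABSENT,
    "present": LABEL_PRESENT,
    "not much": LABEL_PRESENT,
    "very slight or very trace": LABEL_PRESENT,
    "slight or trace": LABEL_PRESENT,
    "intermittent": LABEL_PRESENT,
    "mild": LABEL_PRESENT,
    "mild to moderate": LABEL_PRESENT,
    "moderate": LABEL_PRESENT,
    "moderate to severe": LABEL_PRESENT,
    "significant": LABEL_PRESENT,
    "severe": LABEL_PRESENT,
    "other, or no indicator of size": LABEL_PRESENT,
}


def map_annotation(raw_label: str) -> str:
    """Dichotomize a raw clinician label into ``present``/``absent``.

    Matching is case-insensitive and whitespace-insensitive. Unknown labels
    raise :class:`DataError` listing the accepted vocabulary.
    """
    key = " ".join(str(raw_label).strip().lower().split())
    try:
        return ANNOTATION_MAP[key]
    except KeyError:
        raise DataError(
            f"unrecognized annotation {raw_label!r}; valid labels: "
            f"{sorted(ANNOTATION_MAP)}"
        ) from None


@dataclass
class Recording:
    """A full-body marker trajectory block.

    Attributes
    ----------
    frame_rate : float
        Sampling rate in Hz (120 Hz for the clinical system).
    marker_names : list of str
        Ordered marker names; ``data`` has 3 columns (x, y, z) per marker.
    data : ndarray of shape (n_frames, 3 * n_markers)
        Positions in mm. May contain NaN before gap handling.
    """

    frame_rate: float
    marker_names: list[str]
    data: np.ndarray
    trial_id: str = ""
    task_code: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.frame_rate <= 0:
            raise DataError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.data.ndim != 2:
            raise DataError("data must be 2-D (frames x columns)")
        if len(self.marker_names) == 0:
            raise DataError("recording must contain at least one marker")
        if self.data.shape[1] != 3 * len(self.marker_names):
            raise DataError(
                f"column count {self.data.shape[1]} != 3 x {len(self.marker_names)} markers"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def marker(self, name: str) -> np.ndarray:
        """Return the (n_frames, 3) trajectory of one marker."""
        i = self.marker_names.index(name)
        return self.data[:, 3 * i : 3 * i + 3]


@dataclass
class ExtremityRecording:
    """Marker trajectories belonging to one of the 16 annotated extremities."""

    extremity: str
    frame_rate: float
    marker_names: list[str]
    data: np.ndarray
    label: str | None = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.extremity not in EXTREMITIES:
            raise DataError(
                f"extremity {self.extremity!r} not in the 16-name vocabulary {list(EXTREMITIES)}"
            )
        self.data = np.asarray(self.data, dtype=float)
        if len(self.marker_names) == 0:
            raise DataError("extremity recording must contain at least one marker")
        if self.data.ndim != 2 or self.data.shape[1] != 3 * len(self.marker_names):
            raise DataError("data shape inconsistent with marker list")
        if self.label is not None and self.label not in (LABEL_PRESENT, LABEL_ABSENT):
            raise DataError(f"label must be present/absent, got {self.label!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.frame_rate

    def marker(self, name: str) -> np.ndarray:
        i = self.marker_names.index(name)
        return self.data[:, 3 * i : 3 * i + 3]


# ---------------------------------------------------------------------------
# TRC dialect
# ---------------------------------------------------------------------------

def read_trc(path: str | Path) -> Recording:
    """Read a Motion Analysis style tab-separated ``.trc`` export.

    Positions are returned in mm (a ``Units`` header of ``m`` is converted).
    Empty kinematic cells become NaN; use :func:`fill_gaps` before analysis.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: too short to be a TRC file")
    hdr_fields = lines[1].split("\t")
    hdr_values = lines[2].split("\t")
    if "DataRate" not in hdr_fields[0]:
        raise ParseError(f"{path}: expected DataRate header on line 2")
    hdr = dict(zip(hdr_fields, hdr_values))
    try:
        frame_rate = float(hdr["DataRate"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr.get("Units", "mm").strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed TRC header: {exc}") from exc

    name_cells = lines[3].split("\t")
    if len(name_cells) < 2 or not name_cells[0].startswith("Frame"):
        raise ParseError(f"{path}: expected 'Frame#\\tTime\\t<markers>' on line 4")
    marker_names = [c for c in name_cells[2:] if c.strip()]
    if len(marker_names) != n_markers:
        raise ParseError(
            f"{path}: header declares {n_markers} markers but {len(marker_names)} named"
        )

    n_cols = 3 * n_markers
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[6:], start=7):
        if not line.strip():
            continue
        cells = line.split("\t")
        kin = cells[2 : 2 + n_cols]
        # tolerate trailing blank columns beyond the declared set
        if len(kin) < n_cols:
            raise ParseError(
                f"{path}: line {ln}: expected {n_cols} kinematic columns, got {len(kin)}"
            )
        try:
            rows.append([float(c) if c.strip() else np.nan for c in kin])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric cell ({exc})") from exc
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    if units == "m":
        data = data * 1000.0
    logger.info("read %s: %d frames x %d columns @ %g Hz", path, data.shape[0], data.shape[1], frame_rate)
    return Recording(
        frame_rate=frame_rate,
        marker_names=marker_names,
        data=data,
        trial_id=path.stem,
    )


def write_trc(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` in the TRC dialect accepted by :func:`read_trc`."""
    path = Path(path)
    rec = recording
    n = rec.n_frames
    header = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rec.frame_rate:g}\t{rec.frame_rate:g}\t{n}\t{rec.n_markers}\tmm\t{rec.frame_rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(rec.marker_names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(rec.n_markers)
        ),
        "",
    ]
    t = np.arange(n) / rec.frame_rate
    body = []
    for i in range(n):
        cells = [str(i + 1), f"{t[i]:.6f}"]
        cells += ["" if np.isnan(v) else f"{v:.8f}" for v in rec.data[i]]
        body.append("\t".join(cells))
    path.write_text("\n".join(header + body) + "\n")
    logger.info("wrote %s: %d frames x %d columns", path, n, rec.data.shape[1])


# ---------------------------------------------------------------------------
# Gap handling
# ---------------------------------------------------------------------------

def fill_gaps(recording: Recording, max_gap_s: float = 0.25) -> Recording:
    """Linearly interpolate NaN gaps up to ``max_gap_s``; drop worse markers.

    Clinically delivered files are already interpolated by staff; this guards
    synthetic or degraded inputs. Markers with any gap longer than the limit
    (or NaN at the recording edges) are rejected with a warning.
    """
    max_gap = int(round(max_gap_s * recording.frame_rate))
    keep_names: list[str] = []
    keep_cols: list[np.ndarray] = []
    t = np.arange(recording.n_frames)
    for mi, name in enumerate(recording.marker_names):
        block = recording.data[:, 3 * mi : 3 * mi + 3].copy()
        bad = np.isnan(block).any(axis=1)
        if not bad.any():
            keep_names.append(name)
            keep_cols.append(block)
            continue
        runs = _nan_runs(bad)
        if bad[0] or bad[-1] or max((e - s) for s, e in runs) > max_gap:
            warnings.warn(
                f"marker {name!r} rejected: gap longer than {max_gap_s} s", stacklevel=2
            )
            continue
        good = ~bad
        for ax in range(3):
            block[bad, ax] = np.interp(t[bad], t[good], block[good, ax])
        keep_names.append(name)
        keep_cols.append(block)
    if not keep_names:
        raise DataError("all markers rejected during gap handling")
    return replace(
        recording, marker_names=keep_names, data=np.hstack(keep_cols)
    )


def _nan_runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """Return [start, end) index pairs of consecutive-True runs."""
    runs = []
    start = None
    for i, b in enumerate(bad):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(bad)))
    return runs


# ---------------------------------------------------------------------------
# Extremity splitting and CSV
# ---------------------------------------------------------------------------

def split_by_extremity(
    recording: Recording,
    marker_map: dict[str, str] | None = None,
    label_map: dict[str, str] | None = None,
) -> list[ExtremityRecording]:
    """Group a recording's markers into per-extremity recordings.

    Markers absent from ``marker_map`` are excluded with a warning. Column
    order within each extremity follows the input recording. ``label_map``
    optionally attaches a present/absent label per extremity name.
    """
    marker_map = validate_marker_map(dict(marker_map or DEFAULT_MARKER_MAP))
    groups: dict[str, list[str]] = {}
    for name in recording.marker_names:
        ext = marker_map.get(name)
        if ext is None:
            warnings.warn(f"marker {name!r} has no extremity mapping; excluded", stacklevel=2)
            logger.warning("unmapped marker %r excluded", name)
            continue
        groups.setdefault(ext, []).append(name)
    out = []
    for ext in EXTREMITIES:
        names = groups.get(ext)
        if not names:
            continue
        data = np.hstack([recording.marker(n) for n in names])
        out.append(
            ExtremityRecording(
                extremity=ext,
                frame_rate=recording.frame_rate,
                marker_names=list(names),
                data=data,
                label=(label_map or {}).get(ext),
                trial_id=recording.trial_id,
            )
        )
    return out


def write_extremity_csv(extremity_recording: ExtremityRecording, path: str | Path) -> None:
    """Write one extremity's trajectories as CSV (Frame, Time, marker_axis...)."""
    rec = extremity_recording
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "Frame": np.arange(1, rec.n_frames + 1),
        "Time": np.arange(rec.n_frames) / rec.frame_rate,
    }
    for i, name in enumerate(rec.marker_names):
        for ax, axis in enumerate("xyz"):
            cols[f"{name}_{axis}"] = rec.data[:, 3 * i + ax]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_extremity_csv(
    path: str | Path,
    extremity: str | None = None,
    label: str | None = None,
) -> ExtremityRecording:
    """Read a per-extremity CSV written by :func:`write_extremity_csv`.

    The extremity name is taken from ``extremity`` or parsed from a filename
    of the form ``<trial>__<extremity>.csv``. The frame rate is inferred from
    the Time column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "Time" not in df.columns:
        raise ParseError(f"{path}: missing required 'Time' column")
    marker_cols = [c for c in df.columns if c not in ("Frame", "Time")]
    if not marker_cols or len(marker_cols) % 3:
        raise ParseError(f"{path}: kinematic columns must come in x/y/z triplets")
    bad = [c for c in marker_cols if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ParseError(f"{path}: non-numeric values in columns {bad}")
    t = df["Time"].to_numpy(float)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least two frames to infer frame rate")
    frame_rate = 1.0 / float(np.median(np.diff(t)))
    marker_names = []
    for c in marker_cols[::3]:
        if not c.endswith("_x"):
            raise ParseError(f"{path}: expected '<marker>_x' column, got {c!r}")
        marker_names.append(c[:-2])
    if extremity is None:
        stem = path.stem
        if "__" not in stem:
            raise ParseError(
                f"{path}: cannot infer extremity; pass extremity= or use "
                "'<trial>__<extremity>.csv' naming"
            )
        trial_id, extremity = stem.rsplit("__", 1)
    else:
        trial_id = path.stem
    return ExtremityRecording(
        extremity=extremity,
        frame_rate=frame_rate,
        marker_names=marker_names,
        data=df[marker_cols].to_numpy(float),
        label=label,
        trial_id=trial_id,
    )
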