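"""CSV reading/writing for recordings, annotations and reports.

Recording dialect: comma-separated, UTF-8, header row with columns
``time,ax,ay,az,gx,gy,gz`` (names configurable); time in seconds on a
uniform grid, acceleration in g, angular velocity in rad/s (a ``deg/s``
flag converts on read).  Annotation dialect: ``start_s,end_s,label`` with
half-open intervals and labels Walking / Turning / SittingDown /
StandingUp.

Times and samples are printed with 9 decimal places so that write-read
round trips are stable to better than 1e-9.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError
from .types import (ActivityLabel, ANNOTATION_LABELS, DEFAULT_AXIS_MAP,
                    ImuRecording, Segment, SegmentSet)

IMU_COLUMNS = ("time", "ax", "ay", "az", "gx", "gy", "gz")
ANNOTATION_COLUMNS = ("start_s", "end_s", "label")
_FLOAT_FMT = "%.9f"


def read_imu_csv(path: str | Path,
                 axis_map: Mapping[str, int] | None = None,
                 sample_rate: float = 50.0,
                 columns: Sequence[str] = IMU_COLUMNS,
                 gyro_unit: str = "rad/s") -> ImuRecording:
    """Read a recording CSV; validates columns and the time grid.

    ``columns`` renames the expected seven columns (time, three
    accelerometer, three gyroscope channels), in that order.  Time is
    re-based to start at zero.
    """
    if gyro_unit not in ("rad/s", "deg/s"):
        raise ValidationError("gyro_unit must be 'rad/s' or 'deg/s'")
    if len(columns) != 7:
        raise ValidationError("columns must name 7 fields (time + 6 channels)")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path} has a header but no data rows")
    time = df[columns[0]].to_numpy(dtype=float)
    acc = df[list(columns[1:4])].to_numpy(dtype=float)
    gyro = df[list(columns[4:7])].to_numpy(dtype=float)
    if gyro_unit == "deg/s":
        gyro = np.deg2rad(gyro)
    return ImuRecording(sample_rate=sample_rate, time=time - time[0],
                        acc=acc, gyro=gyro,
                        axis_map=dict(axis_map or DEFAULT_AXIS_MAP),
                        meta={"source": str(path)})


def write_imu_csv(rec: ImuRecording, path: str | Path,
                  columns: Sequence[str] = IMU_COLUMNS) -> None:
    """Write a recording in the CSV dialect read by :func:`read_imu_csv`."""
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.acc, rec.gyro]), columns=list(columns))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_annotations(path: str | Path) -> list[SegmentSet]:
    """Read an annotation CSV into one :class:`SegmentSet` per activity.

    Every activity of the annotation vocabulary is present in the result,
    possibly empty.  Unknown labels and non-positive-length rows raise.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks column(s): {', '.join(missing)}")
    by_label: dict[ActivityLabel, list[Segment]] = {
        lab: [] for lab in ANNOTATION_LABELS}
    valid = {lab.value: lab for lab in ANNOTATION_LABELS}
    for row in df.itertuples(index=False):
        name = str(row.label)
        if name not in valid:
            raise FormatError(f"unknown activity label {name!r} in {path}")
        lab = valid[name]
        start, end = float(row.start_s), float(row.end_s)
        if end <= start:
            raise ValidationError(
                f"row with end_s ({end}) <= start_s ({start}) in {path}")
        by_label[lab].append(Segment(start, end, lab))
    return [SegmentSet(lab, tuple(segs)) for lab, segs in by_label.items()]


def write_annotations(sets: Iterable[SegmentSet], path: str | Path) -> None:
    """Write segment sets as a flat annotation CSV sorted by start time."""
    rows = [(s.start, s.end, s.label.value)
            for ss in sets for s in ss
            if s.label in ANNOTATION_LABELS]
    rows.sort()
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def annotations_to_dict(sets: Iterable[SegmentSet],
                        ) -> dict[ActivityLabel, SegmentSet]:
    """Index segment sets by activity, filling absent activities."""
    out = {lab: SegmentSet(lab) for lab in ANNOTATION_LABELS}
    for ss in sets:
        if ss.label in out and len(ss):
            out[ss.label] = ss
    return out
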