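"""Data model and CSV I/O for wrist-worn IMU recordings.

A recording is a timestamped 6-axis stream (triaxial accelerometer in g,
triaxial gyroscope in degrees/second) from a watch worn on the left wrist.
Axis convention: the y-axis points toward the hand, the x-axis points up
(when looking at the watch face), and the z-axis comes out of the face.

CSV dialect: comma-separated, header ``t,ax,ay,az,gx,gy,gz[,label]``,
UTF-8, '.' decimal; units are seconds, g, and deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AnnotationError,
    FormatError,
    ParameterError,
    SchemaError,
    ShapeError,
)

#: The eight admissible window labels: six posture transitions, a
#: no-movement class, and a pooled other-movement (ADL confounder) class.
LABELS: tuple[str, ...] = (
    "sit_stand",
    "stand_sit",
    "sit_lie",
    "lie_sit",
    "stand_lie",
    "lie_stand",
    "no_movement",
    "other_movement",
)

#: The six transition labels (the closed subset driving the posture timeline).
TRANSITIONS: tuple[str, ...] = LABELS[:6]

#: Source and destination posture of each transition.
TRANSITION_ENDPOINTS: dict[str, tuple[str, str]] = {
    "sit_stand": ("sit", "stand"),
    "stand_sit": ("stand", "sit"),
    "sit_lie": ("sit", "lie"),
    "lie_sit": ("lie", "sit"),
    "stand_lie": ("stand", "lie"),
    "lie_stand": ("lie", "stand"),
}

POSTURES: tuple[str, ...] = ("sit", "stand", "lie")

_CHANNEL_COLUMNS = ("ax", "ay", "az", "gx", "gy", "gz")


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        return a
    raise ShapeError(f"{name} must be one-dimensional")


@dataclass
class IMURecording:
    """A validated 6-axis IMU sample stream.

    ``accel`` and ``gyro`` are (n, 3) arrays; values outside the sensor
    ranges are clipped at construction and counted in ``n_clipped``.
    """

    subject_id: str
    sampling_rate_hz: float
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    accel_range_g: float = 2.0
    gyro_range_dps: float = 300.0
    sample_labels: np.ndarray | None = None  # optional per-sample annotation column
    n_clipped: int = field(default=0)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling_rate_hz must be positive")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.shape != (n, 3):
                raise ShapeError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if self.sample_labels is not None and len(self.sample_labels) != n:
            raise ShapeError("sample_labels length must match timestamps")
        if n > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.sampling_rate_hz) > 0.01 / self.sampling_rate_hz:
                raise FormatError(
                    "median timestamp spacing "
                    f"{med:.6g}s is not within 1% of 1/{self.sampling_rate_hz:g} Hz"
                )
        clipped = int(np.sum(np.abs(self.accel) > self.accel_range_g)) + int(
            np.sum(np.abs(self.gyro) > self.gyro_range_dps)
        )
        if clipped:
            np.clip(self.accel, -self.accel_range_g, self.accel_range_g, out=self.accel)
            np.clip(self.gyro, -self.gyro_range_dps, self.gyro_range_dps, out=self.gyro)
        self.n_clipped += clipped

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class AnnotatedWindow:
    """A fixed-duration labeled movement segment cut from a recording."""

    subject_id: str
    label: str
    sampling_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray
    duration_s: float = 5.0
    padded: bool = False  # True when the window was zero-padded at a recording edge

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ParameterError(f"unknown label {self.label!r}; expected one of {LABELS}")
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = int(round(self.duration_s * self.sampling_rate_hz))
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.shape != (n, 3):
                raise ShapeError(
                    f"{name} must have shape ({n}, 3) for a {self.duration_s:g}s window "
                    f"at {self.sampling_rate_hz:g} Hz, got {arr.shape}"
                )

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]


def read_recording(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    subject_id: str | None = None,
    accel_range_g: float = 2.0,
    gyro_range_dps: float = 300.0,
) -> IMURecording:
    """Read a recording CSV (columns ``t,ax,ay,az,gx,gy,gz[,label]``).

    ``schema`` optionally maps canonical column names to the file's actual
    names. Out-of-range values are clipped and counted (``n_clipped``); the
    sampling rate is inferred from the median timestamp spacing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    schema = dict(schema or {})
    cols = {}
    for canonical in ("t",) + _CHANNEL_COLUMNS:
        actual = schema.get(canonical, canonical)
        if actual not in df.columns:
            raise SchemaError(f"missing column {canonical!r} (looked for {actual!r})")
        cols[canonical] = df[actual].to_numpy(dtype=float)
    t = cols["t"]
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("timestamps must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
        fs = round(fs, 6)
    else:
        fs = 1.0
    label_col = schema.get("label", "label")
    sample_labels = (
        df[label_col].to_numpy(dtype=object) if label_col in df.columns else None
    )
    return IMURecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        sampling_rate_hz=fs,
        timestamps=t,
        accel=np.column_stack([cols["ax"], cols["ay"], cols["az"]]),
        gyro=np.column_stack([cols["gx"], cols["gy"], cols["gz"]]),
        accel_range_g=accel_range_g,
        gyro_range_dps=gyro_range_dps,
        sample_labels=sample_labels,
    )


def write_recording(rec: IMURecording, path: str | Path) -> None:
    """Write a recording CSV; round-trips channel values to 6 decimals."""
    data = {
        "t": rec.timestamps,
        "ax": rec.accel[:, 0],
        "ay": rec.accel[:, 1],
        "az": rec.accel[:, 2],
        "gx": rec.gyro[:, 0],
        "gy": rec.gyro[:, 1],
        "gz": rec.gyro[:, 2],
    }
    if rec.sample_labels is not None:
        data["label"] = rec.sample_labels
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    """Read an annotation sidecar CSV (``start_s,end_s,label``)."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s", "label"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append((float(row.start_s), float(row.end_s), str(row.label)))
    return out


def write_annotations(
    annotations: Sequence[tuple[float, float, str]], path: str | Path
) -> None:
    pd.DataFrame(annotations, columns=["start_s", "end_s", "label"]).to_csv(
        path, index=False
    )


def decimate(rec: IMURecording, target_rate_hz: float) -> IMURecording:
    """Reduce the sampling rate by plain sample dropping (every k-th sample).

    The moving-average noise filter acts as the anti-alias stage upstream;
    dropping samples mimics polling the sensor at the lower rate. Timestamps
    are regenerated on the target-rate grid to avoid drift.
    """
    if target_rate_hz <= 0:
        raise ParameterError("target_rate_hz must be positive")
    k = rec.sampling_rate_hz / target_rate_hz
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ParameterError(
            f"sampling rate {rec.sampling_rate_hz:g} Hz is not an integer multiple "
            f"of target {target_rate_hz:g} Hz"
        )
    k = int(round(k))
    m = int(np.ceil(len(rec) / k)) if len(rec) else 0
    t0 = rec.timestamps[0] if len(rec) else 0.0
    return replace(
        rec,
        sampling_rate_hz=float(target_rate_hz),
        timestamps=t0 + np.arange(m) / target_rate_hz,
        accel=rec.accel[::k].copy(),
        gyro=rec.gyro[::k].copy(),
        sample_labels=None if rec.sample_labels is None else rec.sample_labels[::k].copy(),
        n_clipped=0,
    )
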