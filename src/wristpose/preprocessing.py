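"""Noise filtering, magnitude, and cutting annotated movement windows.

The noise filter is a causal (trailing) moving average, chosen so the same
filter could run in a real-time recognizer: output[i] averages the last
``w`` samples (fewer at the start of the stream). The filter length tracks
the sampling rate (1 s = 100/50/10 points at 100/50/10 Hz), and filtering
is applied to the continuous stream *before* windows are cut.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .exceptions import AnnotationError, ParameterError, ShapeError
from .io import AnnotatedWindow, IMURecording


def moving_average_filter(
    series: np.ndarray, window_s: float, rate_hz: float
) -> np.ndarray:
    """Causal moving average over ``round(window_s * rate_hz)`` samples.

    output[i] = mean(input[max(0, i-w+1) .. i]); the window is shorter at
    the start of the series, so the output has the same length as the input.
    Works on 1-D series or (n, k) channel stacks (filtered along axis 0).
    """
    x = np.asarray(series, dtype=float)
    w = int(round(window_s * rate_hz))
    if w < 1:
        raise ParameterError(f"filter window {window_s:g}s at {rate_hz:g} Hz is empty")
    if x.shape[0] == 0:
        return x.copy()
    c = np.cumsum(x, axis=0)
    out = np.empty_like(x, dtype=float)
    head = min(w, x.shape[0])
    counts = np.arange(1, head + 1, dtype=float)
    if x.ndim > 1:
        counts = counts[:, None]
    out[:head] = c[:head] / counts
    if x.shape[0] > w:
        out[w:] = (c[w:] - c[:-w]) / w
    return out


def magnitude(triad: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a 3-channel triad (n, 3) -> (n,)."""
    a = np.asarray(triad, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ShapeError(f"expected an (n, 3) triad, got shape {a.shape}")
    return np.sqrt(np.sum(a * a, axis=1))


def filter_recording(rec: IMURecording, window_s: float = 1.0) -> IMURecording:
    """Apply the causal moving average to all six channels of a recording."""
    return replace(
        rec,
        accel=moving_average_filter(rec.accel, window_s, rec.sampling_rate_hz),
        gyro=moving_average_filter(rec.gyro, window_s, rec.sampling_rate_hz),
        n_clipped=0,
    )


def cut_windows(
    rec: IMURecording,
    annotations: Sequence[tuple[float, float, str]],
    duration_s: float = 5.0,
) -> list[AnnotatedWindow]:
    """Cut fixed-duration labeled windows centered on annotation midpoints.

    Each window is ``duration_s`` long and centered on the midpoint of its
    (start_s, end_s) annotation. Windows that extend past the recording edge
    are zero-padded and flagged. Apply the noise filter to the recording
    *before* cutting (see :func:`filter_recording`).
    """
    fs = rec.sampling_rate_hz
    n_win = int(round(duration_s * fs))
    n_rec = len(rec)
    t0 = rec.timestamps[0] if n_rec else 0.0
    windows: list[AnnotatedWindow] = []
    for start_s, end_s, label in annotations:
        if end_s <= start_s:
            raise AnnotationError(
                f"annotation end {end_s:g} <= start {start_s:g} for label {label!r}"
            )
        mid = 0.5 * (start_s + end_s)
        i0 = int(round((mid - t0) * fs)) - n_win // 2
        accel = np.zeros((n_win, 3))
        gyro = np.zeros((n_win, 3))
        lo = max(i0, 0)
        hi = min(i0 + n_win, n_rec)
        padded = lo != i0 or hi != i0 + n_win
        if hi > lo:
            accel[lo - i0 : hi - i0] = rec.accel[lo:hi]
            gyro[lo - i0 : hi - i0] = rec.gyro[lo:hi]
        windows.append(
            AnnotatedWindow(
                subject_id=rec.subject_id,
                label=label,
                sampling_rate_hz=fs,
                accel=accel,
                gyro=gyro,
                duration_s=duration_s,
                padded=padded,
            )
        )
    return windows


def windows_from_recording(
    rec: IMURecording,
    annotations: Sequence[tuple[float, float, str]],
    filter_window_s: float = 1.0,
    duration_s: float = 5.0,
) -> list[AnnotatedWindow]:
    """Filter the stream, then cut annotated windows (the standard order)."""
    return cut_windows(filter_recording(rec, filter_window_s), annotations, duration_s)
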