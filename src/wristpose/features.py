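"""The 25-feature bank computed on 7 channels (175 features per window).

Channels: the six sensor axes (ax, ay, az, gx, gy, gz) plus the
acceleration magnitude ``amag``. Per channel, 22 scalar statistics are
computed directly on the series; three further features (eigenvalues of the
dominant directions, the gravity/heading correlation CAGH, and the average
rotation angle) are inherently triad-level and are mapped into per-channel
slots as documented on :func:`triad_orientation_features`, preserving the
25 x 7 bookkeeping.

Conventions (fixed so results are bit-stable):

* standard deviation / variance use the n-1 denominator;
* kurtosis is excess (Fisher) kurtosis m4/m2^2 - 3 and skewness m3/m2^1.5
  with central moments m_k computed with the 1/n convention; a constant
  series falls back to 0 for both;
* the interquartile range uses linear-interpolation quantiles;
* spectral features use the one-sided DFT amplitude spectrum |X_k| for
  k = 1..floor(n/2) — the DC bin is excluded, since posture windows are
  dominated by the gravity offset which would otherwise swamp every
  spectral aggregate.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ShapeError, WindowTooShortError
from .io import AnnotatedWindow
from .preprocessing import magnitude

CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz", "amag")

FEATURE_NAMES: tuple[str, ...] = (
    "min",
    "max",
    "sum",
    "mean",
    "std",
    "kurtosis",
    "skewness",
    "energy",
    "variance",
    "median",
    "rms",
    "avg_difference",
    "iqr",
    "zero_crossing_rate",
    "mean_crossing_rate",
    "eigenvalues",
    "cagh",
    "avg_mean_intensity",
    "avg_rotation_angles",
    "dominant_frequency",
    "peak_difference",
    "peak_rms",
    "root_sum_squares",
    "first_peak",
    "second_peak",
)

#: Canonical 175-column order: feature-major, channel-minor.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{f}__{c}" for f in FEATURE_NAMES for c in CHANNELS
)

_TRIAD_FEATURES = ("eigenvalues", "cagh", "avg_rotation_angles")


def _require_length(x: np.ndarray, n_min: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError("channel series must be one-dimensional")
    if len(x) < n_min:
        raise WindowTooShortError(f"need at least {n_min} samples, got {len(x)}")
    return x


def time_stats(c: np.ndarray) -> dict[str, float]:
    """Time-domain statistics of one channel series (n >= 2)."""
    x = _require_length(c, 2)
    n = len(x)
    mean = float(np.mean(x))
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 > 0:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2 - 3.0
    else:  # constant series
        skew = 0.0
        kurt = 0.0
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "sum": float(np.sum(x)),
        "mean": mean,
        "std": float(np.std(x, ddof=1)),
        "variance": float(np.var(x, ddof=1)),
        "median": float(np.median(x)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "iqr": float(q3 - q1),
        "kurtosis": kurt,
        "skewness": skew,
    }


def avg_pairwise_difference(c: np.ndarray) -> float:
    """Mean |c_i - c_j| over all n(n-1)/2 unordered pairs.

    Computed with the sorted prefix-sum identity
    sum_{i<j} |x_i - x_j| = sum_i (2i - n + 1) * x_(i) (0-based sorted order),
    which is O(n log n) and exactly equal to the double loop.
    """
    x = _require_length(c, 2)
    n = len(x)
    xs = np.sort(x)
    total = float(np.dot(2.0 * np.arange(n) - (n - 1), xs))
    return total / (n * (n - 1) / 2.0)


def crossing_rates(c: np.ndarray) -> dict[str, float]:
    """Zero- and mean-crossing rates; exact zeros do not count as crossings."""
    x = _require_length(c, 2)

    def _zcr(v: np.ndarray) -> float:
        return float(np.sum(v[:-1] * v[1:] < 0)) / (len(v) - 1)

    return {
        "zero_crossing_rate": _zcr(x),
        "mean_crossing_rate": _zcr(x - np.mean(x)),
    }


def spectral_features(c: np.ndarray, rate_hz: float) -> dict[str, float]:
    """Amplitude-spectrum features on |X_k|, k = 1..floor(n/2) (DC excluded).

    * energy — sum of amplitudes;
    * root_sum_squares — sqrt of sum of squared amplitudes;
    * dominant_frequency — rate * k*/n at the largest amplitude (ties: lowest k);
    * spectral peaks — local maxima strictly above both neighbours, ranked by
      amplitude; first/second_peak are the two largest peak amplitudes,
      peak_difference the |f1 - f2| gap in Hz, peak_rms the rms of all peak
      amplitudes (each 0 when too few peaks exist).
    """
    x = _require_length(c, 4)
    n = len(x)
    amps = np.abs(np.fft.rfft(x))[1:]  # k = 1 .. floor(n/2)
    freqs = rate_hz * np.arange(1, len(amps) + 1) / n
    energy = float(np.sum(amps))
    rss = float(np.sqrt(np.sum(amps**2)))
    if energy > 0:
        dom = float(freqs[int(np.argmax(amps))])
    else:
        dom = 0.0
    interior = np.arange(1, len(amps) - 1)
    is_peak = (amps[interior] > amps[interior - 1]) & (amps[interior] > amps[interior + 1])
    peak_idx = interior[is_peak]
    out = {
        "energy": energy,
        "root_sum_squares": rss,
        "dominant_frequency": dom,
        "first_peak": 0.0,
        "second_peak": 0.0,
        "peak_difference": 0.0,
        "peak_rms": 0.0,
    }
    if len(peak_idx):
        order = np.lexsort((peak_idx, -amps[peak_idx]))  # amplitude desc, freq asc
        ranked = peak_idx[order]
        out["first_peak"] = float(amps[ranked[0]])
        out["peak_rms"] = float(np.sqrt(np.mean(amps[peak_idx] ** 2)))
        if len(ranked) > 1:
            out["second_peak"] = float(amps[ranked[1]])
            out["peak_difference"] = float(abs(freqs[ranked[0]] - freqs[ranked[1]]))
    return out


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = np.std(u), np.std(v)
    if su == 0 or sv == 0:
        return 0.0
    return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))


def _cagh(triad: np.ndarray) -> float:
    """Correlation between the gravity-direction and heading-direction components.

    Gravity is estimated as the normalized window-mean vector; heading as the
    dominant eigenvector of the covariance of the triad projected onto the
    plane orthogonal to gravity. Degenerate (zero mean or zero variance)
    windows return 0.
    """
    m = triad.mean(axis=0)
    norm = np.linalg.norm(m)
    if norm == 0:
        return 0.0
    g = m / norm
    proj = triad - np.outer(triad @ g, g)
    cov = np.cov(proj.T, ddof=1)
    w, v = np.linalg.eigh(cov)
    h = v[:, -1]
    return _pearson(triad @ g, triad @ h)


def _avg_rotation_angle(triad: np.ndarray) -> float:
    """Mean angle between each sample vector and the window-mean vector (rad)."""
    m = triad.mean(axis=0)
    m_norm = np.linalg.norm(m)
    if m_norm == 0:
        return 0.0
    norms = np.linalg.norm(triad, axis=1)
    keep = norms > 0
    if not np.any(keep):
        return 0.0
    cosang = (triad[keep] @ m) / (norms[keep] * m_norm)
    return float(np.mean(np.arccos(np.clip(cosang, -1.0, 1.0))))


def triad_orientation_features(
    accel: np.ndarray, gyro: np.ndarray
) -> dict[str, float]:
    """Triad-level orientation features mapped into the per-channel slots.

    * ``eigenvalues``: sorted (descending) eigenvalues of the 3x3 sample
      covariance of the accel triad fill the ax/ay/az slots; likewise for the
      gyro triad into gx/gy/gz; the amag slot carries the accel total
      variance (eigenvalue sum).
    * ``cagh``: the accel gravity/heading correlation replicated into the
      accel slots and amag; the same construction on the gyro triad fills
      the gyro slots.
    * ``avg_rotation_angles``: mean per-sample angle to the mean vector,
      accel-based for ax/ay/az/amag and gyro-based for gx/gy/gz.
    """
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    for name, arr in (("accel", accel), ("gyro", gyro)):
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ShapeError(f"{name} must be an (n, 3) triad")
    if accel.shape[0] != gyro.shape[0]:
        raise ShapeError("accel and gyro triads must have equal length")
    if accel.shape[0] < 3:
        raise WindowTooShortError("triad features need at least 3 samples")

    out: dict[str, float] = {}
    eig_a = np.sort(np.linalg.eigvalsh(np.cov(accel.T, ddof=1)))[::-1]
    eig_g = np.sort(np.linalg.eigvalsh(np.cov(gyro.T, ddof=1)))[::-1]
    for i, ch in enumerate(("ax", "ay", "az")):
        out[f"eigenvalues__{ch}"] = float(eig_a[i])
    for i, ch in enumerate(("gx", "gy", "gz")):
        out[f"eigenvalues__{ch}"] = float(eig_g[i])
    out["eigenvalues__amag"] = float(np.sum(eig_a))

    cagh_a = _cagh(accel)
    cagh_g = _cagh(gyro)
    for ch in ("ax", "ay", "az", "amag"):
        out[f"cagh__{ch}"] = cagh_a
    for ch in ("gx", "gy", "gz"):
        out[f"cagh__{ch}"] = cagh_g

    rot_a = _avg_rotation_angle(accel)
    rot_g = _avg_rotation_angle(gyro)
    for ch in ("ax", "ay", "az", "amag"):
        out[f"avg_rotation_angles__{ch}"] = rot_a
    for ch in ("gx", "gy", "gz"):
        out[f"avg_rotation_angles__{ch}"] = rot_g
    return out


def extract_features(w: AnnotatedWindow) -> pd.Series:
    """Assemble the full 175-entry feature vector for one window.

    Returns a Series indexed by the canonical ``<feature>__<channel>``
    columns; all values are finite (degenerate windows resolve to the
    documented 0 fallbacks). Deterministic given the window and its rate.
    """
    channels = {
        "ax": w.accel[:, 0],
        "ay": w.accel[:, 1],
        "az": w.accel[:, 2],
        "gx": w.gyro[:, 0],
        "gy": w.gyro[:, 1],
        "gz": w.gyro[:, 2],
        "amag": magnitude(w.accel),
    }
    vals: dict[str, float] = {}
    for ch, x in channels.items():
        for name, v in time_stats(x).items():
            vals[f"{name}__{ch}"] = v
        vals[f"avg_difference__{ch}"] = avg_pairwise_difference(x)
        for name, v in crossing_rates(x).items():
            vals[f"{name}__{ch}"] = v
        for name, v in spectral_features(x, w.sampling_rate_hz).items():
            vals[f"{name}__{ch}"] = v
        vals[f"avg_mean_intensity__{ch}"] = float(np.mean(np.abs(x)))
    vals.update(triad_orientation_features(w.accel, w.gyro))
    vec = pd.Series([vals[c] for c in FEATURE_COLUMNS], index=list(FEATURE_COLUMNS))
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise ValueError(f"non-finite features {bad}")
    return vec


def feature_matrix(windows: Iterable[AnnotatedWindow]) -> pd.DataFrame:
    """Stack per-window feature vectors into a windows x features table.

    The result carries the 175 feature columns plus ``label`` and
    ``subject_id`` — the on-disk feature-matrix CSV layout.
    """
    rows, labels, subjects = [], [], []
    for w in windows:
        rows.append(extract_features(w))
        labels.append(w.label)
        subjects.append(w.subject_id)
    M = pd.DataFrame(rows).reset_index(drop=True)
    M["label"] = labels
    M["subject_id"] = subjects
    return M


def feature_columns_of(M: pd.DataFrame) -> list[str]:
    """The feature columns of a matrix (everything but label/subject_id)."""
    return [c for c in M.columns if c not in ("label", "subject_id")]
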