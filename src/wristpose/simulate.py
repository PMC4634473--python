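"""Seeded synthetic wrist-IMU study generator.

Emulates a supervised laboratory collection: 20 subjects, each repeating
every movement class 10 times, recorded by a watch on the left wrist at
100 Hz with a ±2 g accelerometer and ±300 deg/s gyroscope, in 5-s annotated
windows. The wrist's posture change is modelled as a rotation of the
gravity vector between posture-specific canonical orientations in the
sensor frame (y toward the hand, x up, z out of the watch face), with a
raised-cosine angular-velocity profile over a subject-scaled duration
(nominal 2 s inside the 5-s window, so windows contain static pre/post
context). The accelerometer reads the rotated gravity vector plus noise;
the gyroscope reads the rotation's exact kinematic angular velocity plus
noise (no bias-drift model).

Sensor noise model: each sensor's noise is white Gaussian (sd =
``noise_sd_*``) plus a per-window constant bias drawn with the same sd,
standing in for MEMS bias instability and un-modelled motion artifacts.
The bias term matters: white noise alone is averaged away by window-mean
features, so without it the noise parameter would not be a difficulty knob.

ADL confounders are a static posture plus a kind-specific oscillation
(1-4 Hz) on the accelerometer and gyroscope, labelled other_movement;
no_movement is pure static gravity plus noise. Same config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ParameterError
from .io import (
    AnnotatedWindow,
    IMURecording,
    POSTURES,
    TRANSITION_ENDPOINTS,
    TRANSITIONS,
)

#: Canonical gravity direction (unit vector, sensor frame) per posture:
#: standing arm-down puts gravity along +y (toward the hand); sitting with
#: the forearm on the lap puts it out of the watch face (+z); lying with the
#: arm across the body puts it along +x. Simulator parameters, not claims
#: about any particular study.
POSTURE_GRAVITY: dict[str, np.ndarray] = {
    "stand": np.array([0.0, 1.0, 0.0]),
    "sit": np.array([0.0, 0.0, 1.0]),
    "lie": np.array([1.0, 0.0, 0.0]),
}

#: ADL confounders: (posture, oscillation frequency Hz). Frequencies stay
#: below the 5 Hz Nyquist limit of the lowest supported rate (10 Hz).
CONFOUNDERS: dict[str, tuple[str, float]] = {
    "brushing_teeth": ("stand", 3.5),
    "typing": ("sit", 2.5),
    "lifting_cup": ("stand", 1.0),
    "swinging_arms": ("stand", 1.4),
    "adjust_blanket": ("lie", 1.8),
}

_CONF_ACCEL_AMP_G = 0.15
_CONF_GYRO_AMP_DPS = 40.0


@dataclass
class SimConfig:
    """Study-generator configuration (defaults = the emulated protocol)."""

    n_subjects: int = 20
    reps_per_class: int = 10
    rate_hz: float = 100.0
    duration_s: float = 5.0
    transition_s: float = 2.0
    noise_sd_accel: float = 0.03  # g
    noise_sd_gyro: float = 2.0  # deg/s
    subject_speed_range: tuple[float, float] = (0.8, 1.2)
    subject_amplitude_range: tuple[float, float] = (0.8, 1.2)
    orientation_jitter_deg: float = 15.0
    confounders: tuple[str, ...] = tuple(CONFOUNDERS)
    accel_range_g: float = 2.0
    gyro_range_dps: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz not in (100.0, 50.0, 10.0, 100, 50, 10):
            raise ParameterError("rate_hz must be one of 100, 50, 10")
        unknown = set(self.confounders) - set(CONFOUNDERS)
        if unknown:
            raise ParameterError(f"unknown confounder kinds {sorted(unknown)}")


@dataclass
class SubjectParams:
    """Per-subject variation drawn once from the configured ranges."""

    subject_id: str
    speed: float
    amplitude: float
    gravity: dict[str, np.ndarray] = field(default_factory=dict)


def _random_small_rotation(rng: np.random.Generator, max_deg: float) -> Rotation:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    return Rotation.from_rotvec(axis * angle)


def draw_subject(subject_id: str, cfg: SimConfig, rng: np.random.Generator) -> SubjectParams:
    """Draw a subject's speed/amplitude scales and jittered posture poses."""
    speed = rng.uniform(*cfg.subject_speed_range)
    amplitude = rng.uniform(*cfg.subject_amplitude_range)
    gravity = {
        p: _random_small_rotation(rng, cfg.orientation_jitter_deg).apply(
            POSTURE_GRAVITY[p]
        )
        for p in POSTURES
    }
    return SubjectParams(subject_id, speed, amplitude, gravity)


def _noise(
    rng: np.random.Generator, n: int, sd: float
) -> np.ndarray:
    """White noise + a per-window constant bias, both with scale sd, (n, 3)."""
    if sd == 0:
        return np.zeros((n, 3))
    return rng.normal(0.0, sd, size=(n, 3)) + rng.normal(0.0, sd, size=(1, 3))


def _window(
    accel: np.ndarray,
    gyro: np.ndarray,
    label: str,
    subj: SubjectParams,
    cfg: SimConfig,
) -> AnnotatedWindow:
    return AnnotatedWindow(
        subject_id=subj.subject_id,
        label=label,
        sampling_rate_hz=float(cfg.rate_hz),
        accel=np.clip(accel, -cfg.accel_range_g, cfg.accel_range_g),
        gyro=np.clip(gyro, -cfg.gyro_range_dps, cfg.gyro_range_dps),
        duration_s=cfg.duration_s,
    )


def _rotation_segment(
    u: np.ndarray,
    v: np.ndarray,
    t_local: np.ndarray,
    T: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gravity track and body-frame angular velocity for a u -> v rotation.

    The rotation angle follows a raised-cosine rate profile
    omega(t) = (theta/T) * (1 - cos(2 pi t / T)), which starts and ends at
    rest and integrates exactly to theta over [0, T]. Returns the gravity
    unit-vector series (n, 3) and the gyroscope series in deg/s (n, 3).
    """
    cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
    theta = np.arccos(cosang)
    axis = np.cross(u, v)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        # parallel endpoints: no rotation (or pick an arbitrary orthogonal
        # axis for a 180-degree flip)
        if theta < 1e-9:
            g = np.tile(u, (len(t_local), 1))
            return g, np.zeros((len(t_local), 3))
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, u)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        norm = np.linalg.norm(axis)
    axis = axis / norm
    tc = np.clip(t_local, 0.0, T)
    phi = theta * (tc - (T / (2 * np.pi)) * np.sin(2 * np.pi * tc / T)) / T
    rate = np.where(
        (t_local >= 0) & (t_local <= T),
        (theta / T) * (1.0 - np.cos(2 * np.pi * tc / T)),
        0.0,
    )
    g = Rotation.from_rotvec(np.outer(phi, axis)).apply(u)
    gyro_dps = np.rad2deg(-rate)[:, None] * axis[None, :]
    return g, gyro_dps


def simulate_transition(
    kind: str,
    subj: SubjectParams,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> AnnotatedWindow:
    """One 5-s window containing a posture transition (nominal 2 s, centered)."""
    if kind not in TRANSITIONS:
        raise ParameterError(f"unknown transition {kind!r}")
    src, dst = TRANSITION_ENDPOINTS[kind]
    u, v = subj.gravity[src], subj.gravity[dst]
    n = int(round(cfg.duration_s * cfg.rate_hz))
    t = np.arange(n) / cfg.rate_hz
    T = min(cfg.transition_s / subj.speed, cfg.duration_s)
    start = (cfg.duration_s - T) / 2.0
    g, gyro = _rotation_segment(u, v, t - start, T)
    accel = g + _noise(rng, n, cfg.noise_sd_accel)
    gyro = gyro + _noise(rng, n, cfg.noise_sd_gyro)
    return _window(accel, gyro, kind, subj, cfg)


def simulate_confounder(
    kind: str,
    subj: SubjectParams,
    cfg: SimConfig,
    rng: np.random.Generator,
    posture: str | None = None,
) -> AnnotatedWindow:
    """One other_movement window: static posture + kind-specific oscillation."""
    if kind not in CONFOUNDERS:
        raise ParameterError(f"unknown confounder {kind!r}")
    default_posture, freq = CONFOUNDERS[kind]
    posture = posture or default_posture
    if posture not in POSTURES:
        raise ParameterError(f"unknown posture {posture!r}")
    g0 = subj.gravity[posture]
    n = int(round(cfg.duration_s * cfg.rate_hz))
    t = np.arange(n) / cfg.rate_hz
    phase = rng.uniform(0.0, 2 * np.pi)
    osc = np.sin(2 * np.pi * freq * t + phase)
    # drive an axis transverse to gravity so the oscillation shows up on the
    # accelerometer without changing the mean orientation
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, g0)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    drive = np.cross(g0, helper)
    drive /= np.linalg.norm(drive)
    accel = (
        g0[None, :]
        + subj.amplitude * _CONF_ACCEL_AMP_G * osc[:, None] * drive[None, :]
        + _noise(rng, n, cfg.noise_sd_accel)
    )
    gyro = (
        subj.amplitude * _CONF_GYRO_AMP_DPS * osc[:, None] * drive[None, :]
        + _noise(rng, n, cfg.noise_sd_gyro)
    )
    return _window(accel, gyro, "other_movement", subj, cfg)


def simulate_no_movement(
    subj: SubjectParams,
    cfg: SimConfig,
    rng: np.random.Generator,
    posture: str | None = None,
) -> AnnotatedWindow:
    """One no_movement window: static gravity + noise."""
    posture = posture or POSTURES[int(rng.integers(len(POSTURES)))]
    n = int(round(cfg.duration_s * cfg.rate_hz))
    accel = subj.gravity[posture][None, :] + _noise(rng, n, cfg.noise_sd_accel)
    gyro = _noise(rng, n, cfg.noise_sd_gyro)
    return _window(accel, gyro, "no_movement", subj, cfg)


def simulate_study(cfg: SimConfig) -> list[AnnotatedWindow]:
    """Generate the full labeled study: 8 balanced classes per subject.

    Per subject: ``reps_per_class`` windows of each of the six transitions,
    of no_movement, and of other_movement (cycling through the configured
    confounder kinds so every label has equal count, matching the balanced
    collection protocol).
    """
    rng_root = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    streams = rng_root.spawn(cfg.n_subjects)
    windows: list[AnnotatedWindow] = []
    for i, rng in enumerate(streams):
        subj = draw_subject(f"S{i + 1:02d}", cfg, rng)
        for kind in TRANSITIONS:
            for _ in range(cfg.reps_per_class):
                windows.append(simulate_transition(kind, subj, cfg, rng))
        for _ in range(cfg.reps_per_class):
            windows.append(simulate_no_movement(subj, cfg, rng))
        if cfg.confounders:
            for r in range(cfg.reps_per_class):
                kind = cfg.confounders[r % len(cfg.confounders)]
                windows.append(simulate_confounder(kind, subj, cfg, rng))
    return windows


def simulate_recording(
    subject_index: int,
    cfg: SimConfig,
) -> tuple[IMURecording, list[tuple[float, float, str]]]:
    """Render one subject's study as a continuous recording + annotations.

    The subject's windows are chained into a physically continuous stream:
    between consecutive windows a short unannotated "settle" rotation moves
    the wrist from the previous window's final orientation to the next
    window's initial orientation. Emits the same CSV dialects as the I/O
    module, so simulator output feeds the real pipeline unchanged.
    """
    rng_root = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    streams = rng_root.spawn(cfg.n_subjects)
    if not 0 <= subject_index < cfg.n_subjects:
        raise ParameterError("subject_index out of range")
    rng = streams[subject_index]
    subj = draw_subject(f"S{subject_index + 1:02d}", cfg, rng)

    # window plan mirrors simulate_study's per-subject order
    plan: list[tuple[str, str | None]] = []
    for kind in TRANSITIONS:
        plan.extend((kind, None) for _ in range(cfg.reps_per_class))
    plan.extend(("no_movement", None) for _ in range(cfg.reps_per_class))
    if cfg.confounders:
        for r in range(cfg.reps_per_class):
            plan.append(("other_movement", cfg.confounders[r % len(cfg.confounders)]))

    fs = float(cfg.rate_hz)
    settle_s = 1.5
    segments_a: list[np.ndarray] = []
    segments_g: list[np.ndarray] = []
    annotations: list[tuple[float, float, str]] = []
    t_cursor = 0.0
    current_g: np.ndarray | None = None
    for label, conf_kind in plan:
        if label in TRANSITIONS:
            w = simulate_transition(label, subj, cfg, rng)
            g_start = subj.gravity[TRANSITION_ENDPOINTS[label][0]]
            g_end = subj.gravity[TRANSITION_ENDPOINTS[label][1]]
        elif label == "no_movement":
            posture = POSTURES[int(rng.integers(len(POSTURES)))]
            w = simulate_no_movement(subj, cfg, rng, posture=posture)
            g_start = g_end = subj.gravity[posture]
        else:
            w = simulate_confounder(conf_kind, subj, cfg, rng)
            posture = CONFOUNDERS[conf_kind][0]
            g_start = g_end = subj.gravity[posture]
        if current_g is not None:
            n_settle = int(round(settle_s * fs))
            ts = np.arange(n_settle) / fs
            g_track, gyro_track = _rotation_segment(current_g, g_start, ts, settle_s)
            segments_a.append(g_track + _noise(rng, n_settle, cfg.noise_sd_accel))
            segments_g.append(gyro_track + _noise(rng, n_settle, cfg.noise_sd_gyro))
            t_cursor += settle_s
        annotations.append((t_cursor, t_cursor + cfg.duration_s, label))
        segments_a.append(w.accel)
        segments_g.append(w.gyro)
        t_cursor += cfg.duration_s
        current_g = g_end
    accel = np.vstack(segments_a)
    gyro = np.vstack(segments_g)
    rec = IMURecording(
        subject_id=subj.subject_id,
        sampling_rate_hz=fs,
        timestamps=np.arange(len(accel)) / fs,
        accel=accel,
        gyro=gyro,
        accel_range_g=cfg.accel_range_g,
        gyro_range_dps=cfg.gyro_range_dps,
    )
    return rec, annotations
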