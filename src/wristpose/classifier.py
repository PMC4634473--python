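"""Kernel maximum-margin classifier with the Pearson VII universal kernel.

The Pearson VII universal kernel (PUK)

    K(u, v) = 1 / [1 + (2 * ||u - v|| * sqrt(2^(1/omega) - 1) / sigma)^2]^omega

is a distance kernel whose shape parameter omega and width sigma let it
mimic both RBF-like and Lorentzian profiles; omega = sigma = 1 are the
conventional defaults. An RBF alternative is provided for comparison.

Training min-max scales the selected features to [0, 1] using training
statistics only (recorded in the model, with test-time clamping to the
training box), then fits a soft-margin SVM with complexity C on the
precomputed Gram matrix. The quadratic program is delegated to an
established solver (libsvm via scikit-learn); multiclass decisions use
one-vs-one voting with ties broken by aggregate decision value, then by
label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .exceptions import (
    FormatError,
    ParameterError,
    SchemaError,
    ShapeError,
    TrainingError,
)
from .features import feature_columns_of, spectral_features, time_stats
from .io import AnnotatedWindow

MODEL_SCHEMA_VERSION = 1


@dataclass
class KernelSpec:
    """Kernel family and hyperparameters.

    kind: "puk" or "rbf"; omega/sigma are the PUK shape and width;
    gamma is the RBF width (None -> 1/#features at train time);
    complexity_C is the soft-margin penalty (the study value is 100).
    """

    kind: str = "puk"
    omega: float = 1.0
    sigma: float = 1.0
    gamma: float | None = None
    complexity_C: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("puk", "rbf"):
            raise ParameterError(f"unknown kernel kind {self.kind!r}")
        if self.omega <= 0 or self.sigma <= 0 or self.complexity_C <= 0:
            raise ParameterError("kernel parameters must be strictly positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ParameterError("gamma must be strictly positive")


def puk_kernel(u, v, omega: float = 1.0, sigma: float = 1.0) -> float:
    """PUK kernel value for two feature points; K(u, u) = 1, K in (0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ShapeError(f"dimension mismatch: {u.shape} vs {v.shape}")
    d2 = float(np.sum((u - v) ** 2))
    return 1.0 / (1.0 + 4.0 * (2.0 ** (1.0 / omega) - 1.0) * d2 / sigma**2) ** omega


def puk_gram(X: np.ndarray, Y: np.ndarray, omega: float = 1.0, sigma: float = 1.0) -> np.ndarray:
    """PUK Gram matrix between row sets X (n, d) and Y (m, d)."""
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return 1.0 / (1.0 + 4.0 * (2.0 ** (1.0 / omega) - 1.0) * d2 / sigma**2) ** omega


def rbf_gram(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-gamma * d2)


def _gram(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if spec.kind == "puk":
        return puk_gram(X, Y, spec.omega, spec.sigma)
    gamma = spec.gamma if spec.gamma is not None else 1.0 / X.shape[1]
    return rbf_gram(X, Y, gamma)


@dataclass
class TrainedModel:
    """A fitted kernel classifier plus its scaling statistics and features."""

    kernel: KernelSpec
    selected_features: list[str]
    scale_min: np.ndarray
    scale_max: np.ndarray
    classes: np.ndarray
    svc: SVC = field(repr=False)
    train_points: np.ndarray = field(repr=False)  # scaled training rows
    schema_version: int = MODEL_SCHEMA_VERSION

    def _scale(self, X: np.ndarray, clamp: bool) -> np.ndarray:
        rng = self.scale_max - self.scale_min
        safe = np.where(rng == 0, 1.0, rng)
        Xs = (X - self.scale_min) / safe  # constant features map to 0
        if clamp:
            Xs = np.clip(Xs, 0.0, 1.0)
        return Xs

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """One label per row; deterministic; scaling clamps to the training box."""
        missing = [f for f in self.selected_features if f not in rows.columns]
        if missing:
            raise SchemaError(f"rows are missing model features {missing}")
        X = rows[self.selected_features].to_numpy(dtype=float)
        Xs = self._scale(X, clamp=True)
        K = _gram(self.kernel, Xs, self.train_points)
        if len(self.classes) == 2:
            # the binary decision function is sign-flipped relative to the
            # one-vs-one pair columns: positive means the *second* class
            dec = -self.svc.decision_function(K).reshape(-1, 1)
        else:
            dec = self.svc.decision_function(K)
        return self._vote(dec)

    def _vote(self, dec: np.ndarray) -> np.ndarray:
        """One-vs-one majority vote.

        Column order follows the solver's pair enumeration (i, j), i < j in
        class order, with a positive value favouring class i (the libsvm
        convention). Vote ties are broken by the aggregate (summed) decision
        value in the class's favour, then by class order.
        """
        n, n_classes = dec.shape[0], len(self.classes)
        votes = np.zeros((n, n_classes))
        sums = np.zeros((n, n_classes))
        col = 0
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                d = dec[:, col]
                votes[d > 0, i] += 1
                votes[d <= 0, j] += 1
                sums[:, i] += d
                sums[:, j] -= d
                col += 1
        winner = np.empty(n, dtype=int)
        for r in range(n):
            v = votes[r]
            best = np.flatnonzero(v == v.max())
            if len(best) > 1:
                s = sums[r, best]
                best = best[np.flatnonzero(s == s.max())]
            winner[r] = int(best[0])  # residual ties -> class order
        return self.classes[winner]


def train(
    M: pd.DataFrame,
    spec: KernelSpec,
    selected: list[str] | None = None,
) -> TrainedModel:
    """Fit the kernel classifier on a feature matrix.

    ``selected`` restricts and orders the feature columns (None = all).
    Features are min-max scaled to [0, 1] from the training rows only.
    """
    if selected is None:
        selected = feature_columns_of(M)
    missing = [f for f in selected if f not in M.columns]
    if missing:
        raise SchemaError(f"training matrix is missing features {missing}")
    y = M["label"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 classes")
    X = M[list(selected)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise TrainingError("training features contain non-finite values")
    mn = X.min(axis=0)
    mx = X.max(axis=0)
    rng = mx - mn
    Xs = (X - mn) / np.where(rng == 0, 1.0, rng)
    K = _gram(spec, Xs, Xs)
    svc = SVC(
        C=spec.complexity_C,
        kernel="precomputed",
        decision_function_shape="ovo",
        tol=1e-3,
    )
    svc.fit(K, y)
    return TrainedModel(
        kernel=spec,
        selected_features=list(selected),
        scale_min=mn,
        scale_max=mx,
        classes=svc.classes_,
        svc=svc,
        train_points=Xs,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a single archive (versioned schema)."""
    joblib.dump(
        {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kernel": model.kernel,
            "selected_features": model.selected_features,
            "scale_min": model.scale_min,
            "scale_max": model.scale_max,
            "classes": model.classes,
            "svc": model.svc,
            "train_points": model.train_points,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise FormatError(f"unsupported model schema {blob.get('schema_version')}")
    return TrainedModel(
        kernel=blob["kernel"],
        selected_features=blob["selected_features"],
        scale_min=blob["scale_min"],
        scale_max=blob["scale_max"],
        classes=blob["classes"],
        svc=blob["svc"],
        train_points=blob["train_points"],
    )


def adl_baseline_features(w: AnnotatedWindow, use_gyro: bool = False) -> pd.Series:
    """The classic ADL baseline feature set on a 5-s window.

    Per accelerometer axis: mean, standard deviation, spectral energy; plus
    the three pairwise inter-axis Pearson correlations (12 features). With
    ``use_gyro`` the same construction on the gyroscope doubles it to 24.
    Zero-variance axes give correlation 0.
    """
    out: dict[str, float] = {}

    def _block(triad: np.ndarray, names: tuple[str, str, str]) -> None:
        for i, ax in enumerate(names):
            x = triad[:, i]
            st = time_stats(x)
            out[f"mean__{ax}"] = st["mean"]
            out[f"std__{ax}"] = st["std"]
            out[f"energy__{ax}"] = spectral_features(x, w.sampling_rate_hz)["energy"]
        pairs = ((0, 1), (0, 2), (1, 2))
        for i, j in pairs:
            u, v = triad[:, i], triad[:, j]
            su, sv = np.std(u), np.std(v)
            out[f"corr__{names[i]}_{names[j]}"] = (
                float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
                if su > 0 and sv > 0
                else 0.0
            )

    _block(w.accel, ("ax", "ay", "az"))
    if use_gyro:
        _block(w.gyro, ("gx", "gy", "gz"))
    return pd.Series(out)


def adl_feature_matrix(windows, use_gyro: bool = False) -> pd.DataFrame:
    """ADL-baseline feature matrix (12 or 24 columns + label + subject_id)."""
    rows, labels, subjects = [], [], []
    for w in windows:
        rows.append(adl_baseline_features(w, use_gyro=use_gyro))
        labels.append(w.label)
        subjects.append(w.subject_id)
    M = pd.DataFrame(rows).reset_index(drop=True)
    M["label"] = labels
    M["subject_id"] = subjects
    return M
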