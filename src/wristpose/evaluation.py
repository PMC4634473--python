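"""Leave-one-subject-out evaluation and the posture timeline.

LOSOCV holds out every window of one subject per fold, measuring
generalization to unseen people rather than to unseen repetitions. Inside
each fold, feature ranking, min-max scaling, and training see only the
training subjects — the held-out subject never influences any of them.

Per fold, precision and recall are computed per class and averaged with
equal class weight; under the study's balanced design this coincides with
the pooled (micro) variant, which is computed alongside as a cross-check.
The reported score is F = 2PR/(P+R) per held-out subject, averaged across
subjects.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import KernelSpec, train
from .exceptions import (
    EvaluationError,
    OrderingError,
    ParameterError,
    ShapeError,
)
from .io import LABELS, POSTURES, TRANSITION_ENDPOINTS
from .selection import rank_features


def confusion_counts(
    truth: Sequence[str],
    pred: Sequence[str],
    classes: Sequence[str] = LABELS,
) -> pd.DataFrame:
    """Per-class TP/FP/FN/TN counts for a multiclass label comparison.

    A window of true class c predicted as c' != c counts as a false negative
    for c and a false positive for c'.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if len(truth) != len(pred):
        raise ShapeError("truth and pred must have equal length")
    n = len(truth)
    rows = {}
    for c in classes:
        tp = int(np.sum((truth == c) & (pred == c)))
        fn = int(np.sum((truth == c) & (pred != c)))
        fp = int(np.sum((truth != c) & (pred == c)))
        rows[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": n - tp - fp - fn}
    return pd.DataFrame.from_dict(rows, orient="index")[["TP", "FP", "FN", "TN"]]


def f_score(P: float, R: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when P + R = 0."""
    if P + R <= 0:
        return 0.0
    return 2.0 * P * R / (P + R)


def averaged_pr(counts: pd.DataFrame) -> dict[str, float]:
    """Class-averaged and pooled precision/recall from a confusion table.

    Per-class precision TP/(TP+FP) and recall TP/(TP+FN) (0 when the
    denominator is 0) are averaged with equal weight over the classes that
    occur in the truth (TP+FN > 0). The pooled (micro) variant sums counts
    first; the two coincide exactly under balanced classes with every
    prediction inside the class set.
    """
    support = counts["TP"] + counts["FN"]
    present = counts[support > 0]
    if len(present) == 0:
        raise EvaluationError("no positive instances in any class")

    def _safe(num: pd.Series, den: pd.Series) -> pd.Series:
        return (num / den.where(den > 0, 1)).where(den > 0, 0.0)

    prec = _safe(present["TP"], present["TP"] + present["FP"])
    rec = _safe(present["TP"], present["TP"] + present["FN"])
    tp, fp, fn = counts["TP"].sum(), counts["FP"].sum(), counts["FN"].sum()
    return {
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "micro_precision": tp / (tp + fp) if tp + fp else 0.0,
        "micro_recall": tp / (tp + fn) if tp + fn else 0.0,
    }


@dataclass
class EvaluationReport:
    """LOSOCV results: per-subject metrics, pooled confusion, and config."""

    per_subject: pd.DataFrame  # subject, precision, recall, f_score, micro_f, n_windows
    confusion: pd.DataFrame  # pooled per-class TP/FP/FN/TN over all folds
    mean_f: float
    config: dict
    fold_audit: dict[str, int] = field(default_factory=dict)  # subject -> leaked rows
    missing_class_events: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Leave-one-subject-out cross-validation",
            f"  config: {self.config}",
            f"  subjects: {len(self.per_subject)}",
            f"  mean F-score: {self.mean_f:.3f}",
            "",
            self.per_subject.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mean_f": self.mean_f,
            "config": self.config,
            "per_subject": self.per_subject.to_dict(orient="records"),
            "confusion": self.confusion.to_dict(orient="index"),
            "fold_audit": self.fold_audit,
            "missing_class_events": self.missing_class_events,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def losocv(
    M: pd.DataFrame,
    spec: KernelSpec,
    k: int | None = 30,
    discretizer: str = "mdl",
    classes: Sequence[str] = LABELS,
) -> EvaluationReport:
    """Leave-one-subject-out cross-validation of the full pipeline.

    For each subject: rank features (information gain, training folds only,
    skipped when ``k`` is None), fit scaling and the kernel classifier on the
    other subjects, predict the held-out windows, and score. Reports
    per-subject precision/recall/F and their mean, plus pooled confusion
    counts and a fold audit proving zero train/test subject overlap.
    """
    subjects = pd.unique(M["subject_id"])
    if len(subjects) < 2:
        raise ParameterError("LOSOCV needs at least 2 subjects")
    per_subject = []
    pooled = None
    audit: dict[str, int] = {}
    missing: list[str] = []
    for s in subjects:
        test = M[M["subject_id"] == s]
        train_M = M[M["subject_id"] != s]
        audit[str(s)] = int(
            len(set(test["subject_id"]) & set(train_M["subject_id"]))
        )
        selected = rank_features(train_M, k, discretizer=discretizer) if k else None
        model = train(train_M, spec, selected)
        absent = sorted(set(test["label"]) - set(model.classes))
        if absent:
            missing.append(
                f"subject {s}: classes {absent} absent from training folds"
            )
        pred = model.predict(test)
        counts = confusion_counts(test["label"].to_numpy(), pred, classes=classes)
        pr = averaged_pr(counts)
        per_subject.append(
            {
                "subject": str(s),
                "precision": pr["precision"],
                "recall": pr["recall"],
                "f_score": f_score(pr["precision"], pr["recall"]),
                "micro_f": f_score(pr["micro_precision"], pr["micro_recall"]),
                "n_windows": int(len(test)),
            }
        )
        pooled = counts if pooled is None else pooled + counts
    table = pd.DataFrame(per_subject)
    return EvaluationReport(
        per_subject=table,
        confusion=pooled,
        mean_f=float(table["f_score"].mean()),
        config={
            "kernel": spec.kind,
            "C": spec.complexity_C,
            "omega": spec.omega,
            "sigma": spec.sigma,
            "gamma": spec.gamma,
            "k_features": k,
            "discretizer": discretizer if k else None,
            "n_subjects": int(len(subjects)),
        },
        fold_audit=audit,
        missing_class_events=missing,
    )


def _make_sum_exact(occupancy: dict[str, float], target: float) -> None:
    """Adjust the partition in place so ``sum(occupancy.values()) == target``.

    The telescoping occupancy sum is exact in real arithmetic but off by a
    few ulps in floats. The last summand is re-derived and ulp-stepped (a
    correction to an earlier summand gets re-rounded downstream); in the
    rare tie-phase where no value of the last summand can round onto the
    target, an upstream summand is nudged by one ulp to shift the phase.
    """
    keys = list(occupancy)
    last = keys[-1]
    others = keys[:-1]
    for _ in range(20):
        partial = 0.0
        for key in others:
            partial = partial + occupancy[key]
        c = max(target - partial, 0.0)
        for _ in range(8):
            occupancy[last] = c
            residual = target - sum(occupancy.values())
            if residual == 0.0:
                return
            nxt = float(np.nextafter(c, np.inf if residual > 0 else -np.inf))
            if nxt < 0.0:
                break
            c = nxt
        candidates = [k for k in others if occupancy[k] > 0.0]
        if not candidates:
            return
        big = max(candidates, key=lambda k: occupancy[k])
        occupancy[big] = float(np.nextafter(occupancy[big], -np.inf))


@dataclass
class TimelineSummary:
    """State occupancy and transition counts over an evaluated span."""

    occupancy_s: dict[str, float]
    transition_counts: dict[str, int]
    inconsistencies: int
    span: tuple[float, float]


def posture_timeline(
    events: Sequence[tuple[float, str]],
    initial_state: str,
    span: tuple[float, float],
) -> TimelineSummary:
    """Run classified transition events through the 3-state posture machine.

    Each event moves the machine to the transition's destination posture at
    its timestamp; an event whose source posture disagrees with the current
    state still moves to its destination (the classifier's best estimate of
    the new posture) and increments an inconsistency counter. Only the six
    transition labels generate events; no_movement / other_movement windows
    do not change state. Occupancy durations sum exactly to the span.
    """
    t0, t1 = span
    if initial_state not in POSTURES:
        raise ParameterError(f"initial_state must be one of {POSTURES}")
    if t1 < t0:
        raise ParameterError("span end must be >= start")
    occupancy = {p: 0.0 for p in POSTURES}
    transitions: Counter[str] = Counter()
    inconsistencies = 0
    state = initial_state
    t_prev = t0
    last_t = t0
    for t, label in events:
        if label not in TRANSITION_ENDPOINTS:
            raise ParameterError(f"{label!r} is not a transition label")
        if t < last_t:
            raise OrderingError("events must be in non-decreasing time order")
        if not (t0 <= t <= t1):
            raise ParameterError(f"event at t={t:g} outside span {span}")
        last_t = t
        src, dst = TRANSITION_ENDPOINTS[label]
        occupancy[state] += t - t_prev
        if src != state:
            inconsistencies += 1
        state = dst
        transitions[label] += 1
        t_prev = t
    occupancy[state] += t1 - t_prev
    # Fold the floating-point residual of the telescoping sum into the last
    # state of the summation order so the occupancy partition is exactly
    # conservative. The correction must target the final summand (earlier
    # ones get re-rounded downstream) and proceed in single-ulp steps,
    # because a lump correction can oscillate around the target under
    # round-half-even.
    span_length = t1 - t0
    _make_sum_exact(occupancy, span_length)
    return TimelineSummary(
        occupancy_s=occupancy,
        transition_counts=dict(transitions),
        inconsistencies=inconsistencies,
        span=(t0, t1),
    )


def daily_summary(
    events: Sequence[tuple[float, str]],
    initial_state: str,
    span: tuple[float, float],
    day_s: float = 86400.0,
) -> pd.DataFrame:
    """Per-day state occupancy and transition counts (the clinician view).

    The span is split into consecutive days; each day's timeline starts in
    the state the previous day ended in.
    """
    t0, t1 = span
    state = initial_state
    events = list(events)
    rows = []
    day = 0
    start = t0
    while start < t1 or (start == t0 and t1 == t0):
        end = min(start + day_s, t1)
        todays = [(t, lab) for t, lab in events if start <= t < end or (t == t1 == end)]
        tl = posture_timeline(todays, state, (start, end))
        row = {"day": day}
        row.update({f"{p}_s": tl.occupancy_s[p] for p in POSTURES})
        for lab in TRANSITION_ENDPOINTS:
            row[lab] = tl.transition_counts.get(lab, 0)
        row["inconsistencies"] = tl.inconsistencies
        rows.append(row)
        if todays:
            state = TRANSITION_ENDPOINTS[todays[-1][1]][1]
        start = end
        day += 1
        if end == t1:
            break
    return pd.DataFrame(rows)
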