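import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wristpose as wp
from wristpose.exceptions import EvaluationError, OrderingError, ShapeError


class TestConfusionCounts:
    def test_perfect_predictions(self):
        truth = list(wp.LABELS) + ["sit_stand", "stand_sit"]
        counts = wp.confusion_counts(truth, truth)
        assert (counts["FP"] == 0).all() and (counts["FN"] == 0).all()
        assert counts.loc["sit_stand", "TP"] == 2

    def test_misclassification_is_fn_for_truth_and_fp_for_prediction(self):
        counts = wp.confusion_counts(["stand_sit"], ["stand_lie"])
        assert counts.loc["stand_sit", "FN"] == 1
        assert counts.loc["stand_lie", "FP"] == 1
        assert counts.loc["stand_sit", "TP"] == 0

    def test_all_predicted_as_one_class(self):
        truth = list(wp.LABELS)
        pred = ["sit_stand"] * 8
        counts = wp.confusion_counts(truth, pred)
        assert counts.loc["sit_stand", "TP"] == 1
        assert counts.loc["sit_stand", "FP"] == 7
        assert (counts.drop("sit_stand")["FN"] == 1).all()

    def test_support_identity(self, rng):
        truth = rng.choice(wp.LABELS, 60)
        pred = rng.choice(wp.LABELS, 60)
        counts = wp.confusion_counts(truth, pred)
        for c in wp.LABELS:
            assert counts.loc[c, "TP"] + counts.loc[c, "FN"] == np.sum(truth == c)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            wp.confusion_counts(["sit_stand"], [])


class TestFScore:
    @pytest.mark.parametrize("p,r,expected", [(0.7, 0.7, 0.7), (1.0, 0.5, 2 / 3), (0.0, 0.0, 0.0)])
    def test_values(self, p, r, expected):
        assert wp.f_score(p, r) == pytest.approx(expected)

    def test_symmetric_and_monotone(self, rng):
        for _ in range(20):
            p, r = rng.uniform(0.01, 1, 2)
            assert wp.f_score(p, r) == pytest.approx(wp.f_score(r, p))
            assert wp.f_score(min(p + 0.1, 1.0), r) >= wp.f_score(p, r)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_harmonic_mean_lies_between_min_and_max(self, p, r):
        f = wp.f_score(p, r)
        assert 0.0 <= f <= 1.0
        if p > 0 and r > 0:
            assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12


class TestAveragedPr:
    def test_perfect(self):
        counts = wp.confusion_counts(list(wp.LABELS), list(wp.LABELS))
        pr = wp.averaged_pr(counts)
        assert pr["precision"] == 1.0 and pr["recall"] == 1.0

    def test_single_error_balanced_recall(self):
        truth = list(wp.LABELS)
        pred = list(wp.LABELS)
        pred[1] = "stand_lie"
        pr = wp.averaged_pr(wp.confusion_counts(truth, pred))
        assert pr["recall"] == pytest.approx(7 / 8)

    def test_macro_equals_micro_recall_on_balanced_truth(self, rng):
        truth = np.repeat(wp.LABELS, 10)
        for _ in range(10):
            pred = rng.choice(wp.LABELS, len(truth))
            pr = wp.averaged_pr(wp.confusion_counts(truth, pred))
            assert pr["recall"] == pytest.approx(pr["micro_recall"])

    def test_no_positive_instances_rejected(self):
        counts = wp.confusion_counts([], [])
        with pytest.raises(EvaluationError):
            wp.averaged_pr(counts)


def separable_two_subject_matrix():
    """Two clones of the same subject's windows, trivially separable."""
    rows = []
    for subject in ("s1", "s2"):
        for i, label in enumerate(wp.LABELS):
            for r in range(3):
                rows.append(
                    {"f1": float(i), "f2": float(i) + 0.01 * r,
                     "label": label, "subject_id": subject}
                )
    return pd.DataFrame(rows)


class TestLosocv:
    def test_identical_subjects_give_perfect_mean_f(self):
        M = separable_two_subject_matrix()
        report = wp.losocv(M, wp.KernelSpec(), k=None)
        assert report.mean_f == 1.0
        assert len(report.per_subject) == 2

    def test_fold_audit_shows_zero_leakage(self, tiny_matrix):
        report = wp.losocv(tiny_matrix, wp.KernelSpec(), k=30)
        assert set(report.fold_audit.values()) == {0}
        assert len(report.fold_audit) == tiny_matrix["subject_id"].nunique()

    def test_mean_f_is_mean_of_subject_f(self, tiny_matrix):
        report = wp.losocv(tiny_matrix, wp.KernelSpec(), k=20)
        assert report.mean_f == pytest.approx(report.per_subject["f_score"].mean())

    def test_pooled_support_matches_window_counts(self, tiny_matrix):
        report = wp.losocv(tiny_matrix, wp.KernelSpec(), k=20)
        support = report.confusion["TP"] + report.confusion["FN"]
        truth_counts = tiny_matrix["label"].value_counts()
        for c in wp.LABELS:
            assert support[c] == truth_counts.get(c, 0)

    def test_report_serializes_to_json(self, tmp_path, tiny_matrix):
        report = wp.losocv(tiny_matrix, wp.KernelSpec(), k=10)
        path = tmp_path / "report.json"
        report.to_json(path)
        assert path.exists() and '"mean_f"' in path.read_text()


class TestPostureTimeline:
    def test_hand_simulated_occupancy(self):
        tl = wp.posture_timeline(
            [(10.0, "stand_sit"), (20.0, "sit_lie")], "stand", (0.0, 30.0)
        )
        assert tl.occupancy_s == {"sit": 10.0, "stand": 10.0, "lie": 10.0}
        assert tl.transition_counts == {"stand_sit": 1, "sit_lie": 1}
        assert tl.inconsistencies == 0

    def test_no_events_full_span_in_initial_state(self):
        tl = wp.posture_timeline([], "lie", (5.0, 42.0))
        assert tl.occupancy_s["lie"] == 37.0
        assert tl.occupancy_s["sit"] == 0.0

    def test_inconsistent_source_adopts_destination(self):
        tl = wp.posture_timeline([(1.0, "stand_lie")], "sit", (0.0, 2.0))
        assert tl.inconsistencies == 1
        assert tl.occupancy_s["lie"] == 1.0

    def test_out_of_order_events_rejected(self):
        with pytest.raises(OrderingError):
            wp.posture_timeline(
                [(5.0, "stand_sit"), (2.0, "sit_stand")], "stand", (0.0, 10.0)
            )

    def test_occupancy_conserves_span_on_random_sequences(self, rng):
        for _ in range(200):
            t0, t1 = sorted(rng.uniform(0, 1000, 2))
            times = np.sort(rng.uniform(t0, t1, int(rng.integers(0, 20))))
            events = [(float(t), str(rng.choice(wp.TRANSITIONS))) for t in times]
            tl = wp.posture_timeline(events, str(rng.choice(wp.POSTURES)), (t0, t1))
            assert sum(tl.occupancy_s.values()) == t1 - t0

    def test_daily_summary_splits_days_and_carries_state(self):
        events = [(1000.0, "stand_sit"), (90000.0, "sit_lie")]
        table = wp.daily_summary(events, "stand", (0.0, 2 * 86400.0))
        assert len(table) == 2
        assert table.loc[0, "stand_s"] == 1000.0
        assert table.loc[0, "sit_s"] == 86400.0 - 1000.0
        # day 2 starts sitting, lies down at 90000 s
        assert table.loc[1, "sit_s"] == 90000.0 - 86400.0
        assert table.loc[1, "lie_s"] == 2 * 86400.0 - 90000.0
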