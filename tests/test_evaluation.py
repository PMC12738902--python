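"""Detection and counting metrics, including the shipped field-trial table."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabtrack import field_trial_count_table
from cabtrack.evaluation import (
    ConfusionCounts,
    CountTable,
    average_precision,
    count_id_switches,
    evaluate_count_table,
    f1,
    mae,
    mca,
    mean_ap,
    precision,
    recall,
    rmse,
)
from cabtrack.formats import AnnotationRecord, BoundingBox, TransplantState

N = TransplantState.NORMAL
B = TransplantState.BURIED_SEEDLING
R = TransplantState.BARE_ROOT


class TestPrecisionRecallF1:
    def test_balanced_counts(self):
        c = ConfusionCounts(10, 10, 10)
        assert precision(c) == recall(c) == f1(c) == 0.5

    def test_perfect_detector(self):
        c = ConfusionCounts(7, 0, 0)
        assert precision(c) == recall(c) == f1(c) == 1.0

    def test_harmonic_mean_value(self):
        # P=0.8, R=0.6 -> F1 = 2*0.48/1.4 = 24/35
        c = ConfusionCounts(TP=12, FP=3, FN=8)
        assert f1(c) == pytest.approx(24 / 35)

    def test_zero_denominators_reported_absent(self):
        assert precision(ConfusionCounts(0, 0, 5)) is None
        assert recall(ConfusionCounts(0, 5, 0)) is None
        assert f1(ConfusionCounts(0, 5, 5)) is None


def unit_box(i):
    return BoundingBox(10 * i, 0, 10 * i + 8, 8)


def brute_force_ap(tps, n_gt):
    """PR-curve integration by direct enumeration of prefix cutoffs."""
    best = {}
    tp = 0
    for k, is_tp in enumerate(tps, start=1):
        tp += is_tp
        r, p = tp / n_gt, tp / k
        best[r] = max(best.get(r, 0.0), p)
    ap, prev_r, recalls = 0.0, 0.0, sorted(best)
    # monotone envelope from the right
    env = {}
    running = 0.0
    for r in reversed(recalls):
        running = max(running, best[r])
        env[r] = running
    for r in recalls:
        ap += env[r] * (r - prev_r)
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_all_predictions_correct(self):
        gts = [(0, unit_box(i)) for i in range(3)]
        preds = [(0, unit_box(i), 0.9 - 0.1 * i) for i in range(3)]
        assert average_precision(preds, gts) == pytest.approx(1.0)

    def test_high_confidence_hit_shields_later_false_positive(self):
        # one GT; correct at conf 0.9 ranks before the false 0.8 -> AP = 1
        gts = [(0, unit_box(0))]
        preds = [(0, unit_box(0), 0.9), (0, unit_box(5), 0.8)]
        assert average_precision(preds, gts) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_toy_sets(self, rng):
        for _ in range(50):
            n_gt = int(rng.integers(1, 5))
            gts = [(0, unit_box(i)) for i in range(n_gt)]
            n_pred = int(rng.integers(1, 8))
            preds, truth_flags = [], []
            for k in range(n_pred):
                hit = bool(rng.random() < 0.6) and k < n_gt
                box = unit_box(k) if hit else unit_box(20 + k)
                preds.append((0, box, float(1.0 - 0.05 * k)))
                truth_flags.append(1 if hit else 0)
            ap = average_precision(preds, gts)
            assert ap == pytest.approx(brute_force_ap(truth_flags, n_gt))

    def test_no_ground_truth_undefined(self):
        assert average_precision([(0, unit_box(0), 0.9)], []) is None

    def test_mean_ap_is_unweighted_class_mean(self):
        assert mean_ap([1.0, 0.5, 0.0]) == pytest.approx(0.5)


class TestErrorMetrics:
    def test_rmse_of_video1_errors(self):
        assert rmse([6, 2, 1]) == pytest.approx(math.sqrt(41 / 3))
        assert round(rmse([6, 2, 1]), 1) == 3.7

    def test_rmse_of_video4_errors(self):
        assert rmse([10, 4, 1]) == pytest.approx(math.sqrt(39))
        assert round(rmse([10, 4, 1]), 2) == 6.24

    def test_zero_errors(self):
        assert rmse([0, 0, 0]) == 0.0 and mae([0, 0, 0]) == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_rmse_dominates_mae(self, errors):
        assert rmse(errors) >= mae(errors) - 1e-12


class TestMca:
    @pytest.mark.parametrize(
        "manual,predicted,expected",
        [(169, 163, 96.4), (18, 20, 90.0), (9, 8, 88.9), (20, 20, 100.0)],
    )
    def test_printed_cells(self, manual, predicted, expected):
        assert round(mca(manual, predicted), 1) == expected

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        va, vb = mca(a, b), mca(b, a)
        if va is None:
            assert vb is None and a == b == 0
        else:
            assert va == vb and 0.0 <= va <= 100.0

    def test_both_zero_absent(self):
        assert mca(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mca(-1, 5)


@pytest.fixture(scope="module")
def report():
    return evaluate_count_table(field_trial_count_table())


class TestFieldTrialTable:
    """The four-video manual-vs-automated count table regenerates every
    derivable published metric cell."""

    def test_overall_average_mca(self, report):
        assert round(report.overall_average_mca, 1) == 97.8

    def test_per_video_rmse(self, report):
        assert round(report.per_video_rmse["1"], 1) == 3.7
        assert round(report.per_video_rmse["3"], 2) == 1.15
        assert round(report.per_video_rmse["4"], 2) == 6.24

    def test_video2_rmse_is_zero_from_its_own_counts(self, report):
        # video 2 has identical manual and automated counts in every
        # category, so its RMSE is exactly 0 (the published 0.58 cannot be
        # derived from the published counts)
        assert report.per_video_rmse["2"] == 0.0

    def test_per_video_total_mca(self, report):
        assert round(report.per_video_total_mca["1"], 1) == 97.4
        assert report.per_video_total_mca["2"] == 100.0
        assert round(report.per_video_total_mca["3"], 1) == 97.6
        assert round(report.per_video_total_mca["4"], 1) == 96.2

    def test_per_category_mca(self, report):
        assert round(report.per_category_mca[N], 1) == 97.4
        assert round(report.per_category_mca[B], 1) == 94.3
        assert round(report.per_category_mca[R], 1) == 88.7

    def test_per_category_mae(self, report):
        assert report.per_category_mae[N] == 4.0
        assert report.per_category_mae[B] == 1.5
        assert report.per_category_mae[R] == 1.0

    def test_per_category_rmse(self, report):
        assert round(report.per_category_rmse[N], 2) == 5.83
        assert round(report.per_category_rmse[B], 2) == 2.24
        # sqrt(1.5) = 1.2247...; the published table prints 1.23 (rounded
        # up through an intermediate 1.225), so compare within 0.01
        assert report.per_category_rmse[R] == pytest.approx(
            math.sqrt(1.5)
        ) == pytest.approx(1.23, abs=0.01)

    def test_zero_zero_cell_excluded_from_category_mean(self):
        # video 2's bare-root row is 0/0: its MCA is undefined and must not
        # drag the category mean down
        table = field_trial_count_table()
        assert mca(*table.data["2"][R]) is None

    def test_perfect_single_video(self):
        table = CountTable({"v": {N: (10, 10), B: (2, 2), R: (1, 1)}})
        rep = evaluate_count_table(table)
        assert rep.overall_average_mca == 100.0
        assert rep.per_video_rmse["v"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CountTable({})


class TestIdSwitches:
    def test_stable_tracking_has_zero_switches(self):
        truth, tracks = [], []
        for f in range(5):
            truth.append(AnnotationRecord(f, N, 1, BoundingBox(0, f, 10, f + 10)))
            tracks.append(AnnotationRecord(f, N, 42, BoundingBox(0, f, 10, f + 10)))
        assert count_id_switches(truth, tracks) == 0

    def test_mid_sequence_id_change_counts_one_switch(self):
        truth, tracks = [], []
        for f in range(6):
            truth.append(AnnotationRecord(f, N, 1, BoundingBox(0, f, 10, f + 10)))
            tid = 42 if f < 3 else 43
            tracks.append(AnnotationRecord(f, N, tid, BoundingBox(0, f, 10, f + 10)))
        assert count_id_switches(truth, tracks) == 1
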