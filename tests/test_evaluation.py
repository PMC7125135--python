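import numpy as np
import pandas as pd
import pytest

from nonwear import (
    ChoiParams,
    MinuteLabels,
    TroianoParams,
    choi,
    f1_score,
    filter_day_phase,
    metrics_from_counts,
    run_grid,
    score_minutes,
    troiano,
    tune_cv,
)
from nonwear.core import ConfusionCounts
from nonwear.evaluation import confusion_counts, pooled_counts

from conftest import T0, counts_from_axis
from oracles import confusion_loop

W, N = 0, 1


class TestScoreMinutes:
    def test_worked_example(self):
        truth = [W, W, N, N, N, W]
        predicted = [W, N, N, W, W, W]
        counts, metrics = score_minutes(truth, predicted)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 2, 1, 2)
        assert metrics.precision == pytest.approx(0.5)
        assert metrics.recall == pytest.approx(1 / 3)
        assert metrics.accuracy == pytest.approx(0.5)
        assert metrics.f1 == pytest.approx(0.4)

    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 2, 50)
        _, metrics = score_minutes(truth, truth)
        assert metrics.accuracy == metrics.precision == metrics.recall == metrics.f1 == 1.0

    def test_matches_loop_oracle_with_conservation(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 21))
            truth = rng.integers(0, 2, n)
            predicted = rng.integers(0, 2, n)
            counts, _ = score_minutes(truth, predicted)
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == confusion_loop(
                truth, predicted
            )
            assert counts.total == n

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            score_minutes([0, 1], [0, 1, 0])

    def test_degenerate_denominators(self):
        # empty prediction: precision 0; no positives in truth: recall 0
        _, m = score_minutes([N, N], [W, W])
        assert m.precision == 0.0 and m.f1 == 0.0
        _, m = score_minutes([W, W], [W, W])
        assert m.recall == 0.0 and m.precision == 0.0 and m.accuracy == 1.0


class TestF1:
    @pytest.mark.parametrize(
        "p,r,expected", [(1, 1, 1.0), (0, 0.8, 0.0), (0.5, 1 / 3, 0.4), (0, 0, 0.0)]
    )
    def test_values(self, p, r, expected):
        assert f1_score(p, r) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)


class TestDayPhaseFilter:
    def test_recording_inside_day_phase_unchanged(self):
        labels = MinuteLabels("2020-01-06 08:00", np.arange(60) % 2)
        out = filter_day_phase(labels)
        np.testing.assert_array_equal(out.values, labels.values)
        assert out.start_time == labels.start_time

    def test_recording_at_night_empty(self):
        labels = MinuteLabels("2020-01-06 01:00", np.ones(60, dtype=int))
        assert len(filter_day_phase(labels)) == 0

    def test_24h_from_midnight_keeps_16_hours(self):
        labels = MinuteLabels("2020-01-06 00:00", np.zeros(1440, dtype=int))
        out = filter_day_phase(labels)
        assert len(out) == 16 * 60
        assert out.start_time == pd.Timestamp("2020-01-06 07:00")

    def test_same_mask_applies_to_truth_and_prediction(self, rng):
        truth = MinuteLabels("2020-01-06 05:30", rng.integers(0, 2, 300))
        pred = MinuteLabels("2020-01-06 05:30", rng.integers(0, 2, 300))
        t2, p2 = filter_day_phase(truth), filter_day_phase(pred)
        assert len(t2) == len(p2)
        counts, _ = score_minutes(t2, p2)
        assert counts.total == len(t2)


def _dominance_dataset():
    """Sedentary bouts of 30-60 zero minutes (wear) around one genuine long
    non-wear stretch: a 120-min Troiano interval beats a 1-min interval."""
    rng = np.random.default_rng(0)
    series, truth = [], []
    for _ in range(4):
        counts = []
        labels = []
        for _ in range(6):  # active bout then sedentary bout
            counts += [int(rng.integers(200, 2000))] * int(rng.integers(5, 15))
            counts += [0] * int(rng.integers(30, 61))
        labels = [0] * len(counts)
        counts += [0] * 180  # true non-wear tail
        labels += [1] * 180
        series.append(counts_from_axis(np.array(counts)))
        truth.append(MinuteLabels(T0, np.array(labels)))
    return list(zip(series, truth))


class TestRunGrid:
    def test_single_combination(self):
        dataset = _dominance_dataset()
        result = run_grid("troiano", {"min_interval": [60]}, dataset)
        assert len(result.table) == 1
        assert result.best["f1"] == 0

    def test_long_interval_dominates_on_f1(self):
        dataset = _dominance_dataset()
        result = run_grid("troiano", {"min_interval": [1, 120]}, dataset)
        assert result.best_params("f1")["min_interval"] == 120
        # verify both rows independently by direct scoring
        for interval, row in zip([1, 120], result.table.itertuples()):
            total = ConfusionCounts(0, 0, 0, 0)
            for series, truth in dataset:
                pred = troiano(series, TroianoParams(min_interval=interval))
                total = total + confusion_counts(truth, pred)
            m = metrics_from_counts(total)
            assert row.f1 == pytest.approx(m.f1)
            assert (row.tp, row.fp) == (total.tp, total.fp)

    def test_dataset_duplication_leaves_metrics_unchanged(self):
        dataset = _dominance_dataset()
        grid = {"min_interval": [60, 120]}
        once = run_grid("troiano", grid, dataset)
        twice = run_grid("troiano", grid, dataset + dataset)
        for metric in ("accuracy", "precision", "recall", "f1"):
            np.testing.assert_allclose(once.table[metric], twice.table[metric])

    def test_row_order_is_lexicographic(self):
        dataset = _dominance_dataset()
        result = run_grid(
            "troiano", {"min_interval": [30, 60], "spikes_allowed": [0, 2]}, dataset
        )
        rows = list(zip(result.table.min_interval, result.table.spikes_allowed))
        assert rows == [(30, 0), (30, 2), (60, 0), (60, 2)]

    def test_invalid_combinations_skipped(self, caplog):
        dataset = _dominance_dataset()
        with caplog.at_level("WARNING"):
            result = run_grid("troiano", {"min_interval": [0, 60]}, dataset)
        assert len(result.table) == 1
        assert "skipping" in caplog.text

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            run_grid("troiano", {"window": [30]}, _dominance_dataset())


def _cv_dataset(rng, n=20):
    """Recordings where min_interval=60 dominates 210 (episodes of ~90 min),
    with a few all-wear recordings to populate the second stratum."""
    dataset = []
    for i in range(n):
        counts = rng.integers(100, 500, 400)
        labels = np.zeros(400, dtype=int)
        if i % 4 != 0:
            s = int(rng.integers(0, 300))
            counts[s : s + 95] = 0
            labels[s : s + 95] = 1
        dataset.append((counts_from_axis(counts), MinuteLabels(T0, labels)))
    return dataset


class TestTuneCv:
    def test_single_combination_reported(self, rng):
        dataset = _cv_dataset(rng)
        result = tune_cv("troiano", {"min_interval": [60]}, dataset, k=3, seed=0)
        assert result.chosen == {"min_interval": 60}
        assert len(result.folds) == 3
        assert {"f1", "test_indices"} <= set(result.folds.columns)

    def test_dominant_params_win_every_fold(self, rng):
        dataset = _cv_dataset(rng)
        result = tune_cv(
            "troiano", {"min_interval": [60, 210]}, dataset, k=5, seed=1
        )
        assert result.chosen == {"min_interval": 60}
        assert (result.folds["min_interval"] == 60).all()

    def test_selection_matches_exhaustive_recomputation(self, rng):
        dataset = _cv_dataset(rng)
        grid = {"min_interval": [60, 210]}
        result = tune_cv("troiano", grid, dataset, k=4, seed=7)
        for row in result.folds.itertuples():
            train = [dataset[i] for i in row.train_indices]
            test = [dataset[i] for i in row.test_indices]
            # independent per-fold recomputation of winner and test metrics
            best_f1, best_params = -1.0, None
            for interval in grid["min_interval"]:
                m = metrics_from_counts(
                    pooled_counts("troiano", TroianoParams(min_interval=interval), train)
                )
                if m.f1 > best_f1:
                    best_f1, best_params = m.f1, interval
            assert row.min_interval == best_params
            m_test = metrics_from_counts(
                pooled_counts(
                    "troiano", TroianoParams(min_interval=best_params), test
                )
            )
            assert row.f1 == pytest.approx(m_test.f1)

    def test_deterministic_under_seed(self, rng):
        dataset = _cv_dataset(rng)
        grid = {"min_interval": [60, 210]}
        a = tune_cv("troiano", grid, dataset, k=4, seed=3)
        b = tune_cv("troiano", grid, dataset, k=4, seed=3)
        pd.testing.assert_frame_equal(a.folds, b.folds)
        assert a.chosen == b.chosen

    def test_empty_stratum_rejected(self, rng):
        dataset = _cv_dataset(rng)
        all_nonwear = [d for d in dataset if d[1].values.any()]
        with pytest.raises(ValueError, match="without non-wear"):
            tune_cv("troiano", {"min_interval": [60]}, all_nonwear, k=2, seed=0)


def test_micro_average_equals_metrics_of_summed_counts(rng):
    parts = [
        confusion_counts(rng.integers(0, 2, 100), rng.integers(0, 2, 100))
        for _ in range(5)
    ]
    total = ConfusionCounts(0, 0, 0, 0)
    for c in parts:
        total = total + c
    pooled = metrics_from_counts(total)
    assert pooled.precision == pytest.approx(total.tp / (total.tp + total.fp))
    assert pooled.recall == pytest.approx(total.tp / (total.tp + total.fn))
    assert pooled.accuracy == pytest.approx((total.tp + total.tn) / total.total)


def test_fp_monotone_in_interval_ladder(rng):
    """Zero-run tolerance: longer minimum intervals never add false positives."""
    counts = rng.integers(0, 300, 600)
    counts[rng.random(600) < 0.75] = 0
    truth = MinuteLabels(T0, np.zeros(600, dtype=int))
    for algo, cls in ((troiano, TroianoParams), (choi, ChoiParams)):
        prev = None
        for interval in (30, 60, 90, 140, 210):
            c, _ = score_minutes(truth, algo(counts_from_axis(counts), cls(min_interval=interval)))
            if prev is not None:
                assert c.fp <= prev
            prev = c.fp
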