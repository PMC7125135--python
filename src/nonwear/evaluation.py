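"""Minute-wise scoring, day-phase filtering, grid sweeps, and CV tuning.

Scoring treats every minute as an independent binary decision with non-wear
as the positive class.  Metrics pooled across recordings are micro-averaged:
confusion counts are summed first and the ratios computed once, matching the
minute-level framing of the evaluation (no averaging-of-ratios).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd

from .core import ConfusionCounts, EpochCountSeries, Metrics, MinuteLabels, TriaxialRecording
from .epoch_algorithms import ChoiParams, HechtParams, TroianoParams, choi, hecht, troiano
from .raw_algorithm import HeesParams, hees

logger = logging.getLogger(__name__)

ALGORITHMS = {
    "hecht": (hecht, HechtParams),
    "troiano": (troiano, TroianoParams),
    "choi": (choi, ChoiParams),
    "hees": (hees, HeesParams),
}


def _label_values(labels) -> np.ndarray:
    if isinstance(labels, MinuteLabels):
        return labels.values
    return np.asarray(labels).astype(np.uint8)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 when both inputs are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, F1 from pooled confusion counts.

    Degenerate denominators resolve to 0 (an algorithm that predicts nothing
    earns precision 0, not an undefined value), penalizing empty predictions
    consistently.
    """
    total = c.total
    accuracy = (c.tp + c.tn) / total if total else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return Metrics(accuracy, precision, recall, f1_score(precision, recall))


def confusion_counts(truth, predicted) -> ConfusionCounts:
    t = _label_values(truth).astype(bool)
    p = _label_values(predicted).astype(bool)
    if t.shape != p.shape:
        raise ValueError(
            f"label length mismatch: truth {t.shape[0]}, predicted {p.shape[0]}"
        )
    return ConfusionCounts(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def score_minutes(truth, predicted) -> tuple[ConfusionCounts, Metrics]:
    """Minute-wise confusion counts and derived metrics (positive = non-wear)."""
    counts = confusion_counts(truth, predicted)
    return counts, metrics_from_counts(counts)


def _minutes_of_day(labels: MinuteLabels) -> np.ndarray:
    start = labels.start_time
    offset = start.hour * 60 + start.minute
    return (offset + np.arange(len(labels))) % 1440


def filter_day_phase(
    labels: MinuteLabels, start_clock: str = "07:00", end_clock: str = "23:00"
) -> MinuteLabels:
    """Restrict a label vector to minutes whose clock time falls in the day
    phase ``[start_clock, end_clock)``; order is preserved.

    The result concatenates the retained minutes (it is generally not
    contiguous in time); its start time is the first retained minute.  Apply
    the same filter to truth and prediction before scoring.
    """

    def clock(s: str) -> int:
        h, m = s.split(":")
        return int(h) * 60 + int(m)

    lo, hi = clock(start_clock), clock(end_clock)
    mod = _minutes_of_day(labels)
    keep = (mod >= lo) & (mod < hi) if lo <= hi else (mod >= lo) | (mod < hi)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return MinuteLabels(labels.start_time, np.zeros(0, dtype=np.uint8))
    start = labels.start_time + pd.to_timedelta(int(idx[0]), unit="min")
    return MinuteLabels(start, labels.values[keep])


# ---------------------------------------------------------------------------
# grid sweeps
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    """Sweep output: one table row per parameter combination, plus the
    argmax row index per metric (first row wins ties)."""

    algorithm: str
    param_names: list[str]
    table: pd.DataFrame
    best: dict[str, int]

    def best_params(self, metric: str = "f1") -> dict:
        row = self.table.loc[self.best[metric]]
        return {
            name: (row[name].item() if hasattr(row[name], "item") else row[name])
            for name in self.param_names
        }


def _run_algorithm(algorithm: str, params, data) -> MinuteLabels:
    func, _ = ALGORITHMS[algorithm]
    return func(data, params)


def pooled_counts(algorithm: str, params, dataset) -> ConfusionCounts:
    """Confusion counts pooled over a dataset of (input, truth) pairs."""
    total = ConfusionCounts(0, 0, 0, 0)
    for data, truth in dataset:
        predicted = _run_algorithm(algorithm, params, data)
        total = total + confusion_counts(truth, predicted)
    return total


def run_grid(algorithm: str, grid: dict[str, list], dataset) -> GridResult:
    """Exhaustive sweep over the cartesian product of the grid value lists.

    ``dataset`` is a list of ``(input, truth)`` pairs where the input is an
    :class:`EpochCountSeries` (hecht/troiano/choi) or a
    :class:`TriaxialRecording` (hees).  Counts are pooled across recordings
    before metrics are computed.  Rows appear in lexicographic order over the
    value lists as given; invalid parameter combinations are skipped with a
    logged reason.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if not grid:
        raise ValueError("grid must be non-empty")
    if not dataset:
        raise ValueError("dataset must be non-empty")
    _, params_cls = ALGORITHMS[algorithm]
    valid_fields = {f.name for f in dataclass_fields(params_cls)}
    unknown = set(grid) - valid_fields
    if unknown:
        raise ValueError(f"unknown hyperparameters for {algorithm}: {sorted(unknown)}")
    names = list(grid.keys())
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        assignment = dict(zip(names, combo))
        try:
            params = params_cls(**assignment).validate()
        except ValueError as err:
            logger.warning("skipping combination %s: %s", assignment, err)
            continue
        counts = pooled_counts(algorithm, params, dataset)
        metrics = metrics_from_counts(counts)
        rows.append(
            {**assignment, "tp": counts.tp, "tn": counts.tn, "fp": counts.fp,
             "fn": counts.fn, **metrics.as_dict()}
        )
    if not rows:
        raise ValueError("no valid parameter combinations in the grid")
    table = pd.DataFrame(rows)
    best = {
        metric: int(table[metric].to_numpy().argmax())
        for metric in ("accuracy", "precision", "recall", "f1")
    }
    return GridResult(algorithm, names, table, best)


# ---------------------------------------------------------------------------
# cross-validated tuning
# ---------------------------------------------------------------------------


@dataclass
class TuneResult:
    """Chosen parameter set plus the per-repetition test metrics."""

    algorithm: str
    chosen: dict
    folds: pd.DataFrame


def _stratified_holdout(
    strata: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One recording-level stratified train/test split."""
    train_idx, test_idx = [], []
    for value in np.unique(strata):
        members = np.flatnonzero(strata == value)
        rng.shuffle(members)
        n_test = max(1, int(round((1 - train_frac) * members.size)))
        n_test = min(n_test, members.size)
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def tune_cv(
    algorithm: str,
    grid: dict[str, list],
    dataset,
    k: int = 10,
    train_frac: float = 0.7,
    seed: int | None = None,
) -> TuneResult:
    """Repeated stratified holdout tuning.

    Performs ``k`` repetitions of recording-level stratified
    ``train_frac``/(1 - ``train_frac``) splits, stratifying on whether a
    recording contains any true non-wear.  Per repetition, the F1-argmax
    parameter set on the training recordings is evaluated on the held-out
    recordings.  The final choice is the modal winning parameter set, ties
    broken by the highest mean test F1.  Deterministic under a fixed seed.

    (Described in the source literature as "10-fold cross-validation with
    70/30 splits" — an internally contradictory phrase; repeated stratified
    holdouts are what those proportions admit.)
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    strata = np.array(
        [int(_label_values(truth).any()) for _, truth in dataset]
    )
    for value, name in ((1, "with non-wear"), (0, "without non-wear")):
        if not (strata == value).any():
            raise ValueError(f"stratum '{name}' is empty")
    rng = np.random.default_rng(seed)
    fold_rows = []
    winners: list[tuple] = []
    for fold in range(k):
        train_idx, test_idx = _stratified_holdout(strata, train_frac, rng)
        train = [dataset[i] for i in train_idx]
        test = [dataset[i] for i in test_idx]
        result = run_grid(algorithm, grid, train)
        params_dict = result.best_params("f1")
        _, params_cls = ALGORITHMS[algorithm]
        params = params_cls(**params_dict).validate()
        counts = pooled_counts(algorithm, params, test)
        metrics = metrics_from_counts(counts)
        winners.append(tuple(sorted(params_dict.items())))
        fold_rows.append(
            {
                "fold": fold,
                **params_dict,
                **metrics.as_dict(),
                "train_indices": tuple(int(i) for i in sorted(train_idx)),
                "test_indices": tuple(int(i) for i in sorted(test_idx)),
            }
        )
    folds = pd.DataFrame(fold_rows)
    # modal winner; ties -> highest mean test F1, then first occurrence
    tally: dict[tuple, list] = {}
    for w, row in zip(winners, fold_rows):
        tally.setdefault(w, []).append(row["f1"])
    order = sorted(
        tally.items(),
        key=lambda kv: (-len(kv[1]), -float(np.mean(kv[1])), winners.index(kv[0])),
    )
    chosen = dict(order[0][0])
    return TuneResult(algorithm, chosen, folds)
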