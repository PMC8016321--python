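"""Relevance-ranked variable ablation.

The trained network is *never retrained*: day-2 stride patterns are
re-evaluated with all but the top-k relevance-ranked variables set to 0
(the participant-mean value in the standardized, [-1, 1]-rescaled feature
representation), producing the accuracy-vs-number-of-variables curve.
Whole-channel subsets (e.g. the five most identity-bearing trajectories,
500 variables) are evaluated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .channels import N_FEATURES, N_SAMPLES, channel_index
from .classifier import AccuracyReport, NetworkModel, participant_accuracy, predict
from .relevance import AggregatedRelevance

#: grid anchored at the quoted landmarks 16, 200, 500 and the full 1200
DEFAULT_K_GRID: tuple[int, ...] = (16, 25, 50, 100, 200, 300, 500, 800, 1200)


@dataclass(frozen=True)
class AccuracyCurve:
    """Mean accuracy as a function of the number of retained variables."""

    k_values: tuple[int, ...]
    accuracies: tuple[float, ...]  # unweighted participant-mean, percent
    retained_sets: tuple[tuple[int, ...], ...]  # nested: set(k1) subset of set(k2)
    baseline_full: float  # accuracy with all 1200 variables

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.k_values, self.k_values[1:])):
            raise ValueError("k values must be strictly increasing")
        for small, large in zip(self.retained_sets, self.retained_sets[1:]):
            if not set(small) <= set(large):
                raise ValueError("retained sets must be nested")


def rank_variables(agg: AggregatedRelevance) -> np.ndarray:
    """Feature indices sorted by descending relevance, ties by ascending index."""
    values = np.asarray(agg.values, dtype=float)
    return np.argsort(-values, kind="stable")


def mask_patterns(patterns: np.ndarray, retained_indices: Sequence[int]) -> np.ndarray:
    """Zero all variables outside ``retained_indices`` (input not mutated)."""
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    idx = np.asarray(retained_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= N_FEATURES):
        raise IndexError(f"retained indices must lie in [0, {N_FEATURES})")
    masked = np.zeros_like(X)
    masked[:, idx] = X[:, idx]
    return masked


def _mean_accuracy(
    model: NetworkModel, X: np.ndarray, labels: np.ndarray
) -> AccuracyReport:
    pred, _ = predict(model, X)
    return participant_accuracy(pred, labels, classes=model.classes)


def ablation_curve(
    model: NetworkModel,
    patterns: np.ndarray,
    labels: np.ndarray,
    agg: AggregatedRelevance,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
) -> AccuracyCurve:
    """Accuracy-vs-#variables curve over nested top-k relevance subsets.

    For each k the day-2 patterns are masked to the k top-ranked variables
    and re-evaluated with the unchanged trained model.  ``k = len(features)``
    reproduces the full evaluation exactly (identity mask).
    """
    if len(k_grid) == 0:
        raise ValueError("k grid must not be empty")
    ks = sorted(int(k) for k in k_grid)
    if ks[0] < 0 or ks[-1] > N_FEATURES:
        raise ValueError(f"k values must lie in [0, {N_FEATURES}]")
    order = rank_variables(agg)
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    accs, sets = [], []
    for k in ks:
        retained = tuple(int(i) for i in np.sort(order[:k]))
        report = _mean_accuracy(model, mask_patterns(X, retained), labels)
        accs.append(report.mean_accuracy)
        sets.append(retained)
    baseline = _mean_accuracy(model, X, labels).mean_accuracy
    return AccuracyCurve(
        k_values=tuple(ks),
        accuracies=tuple(accs),
        retained_sets=tuple(sets),
        baseline_full=baseline,
    )


def channel_subset_accuracy(
    model: NetworkModel,
    patterns: np.ndarray,
    labels: np.ndarray,
    channels: Sequence[str],
) -> float:
    """Mean accuracy keeping only whole named channels (100 samples each)."""
    idx = []
    for name in channels:
        c = channel_index(name)  # raises KeyError for unknown channels
        idx.extend(range(c * N_SAMPLES, (c + 1) * N_SAMPLES))
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    return _mean_accuracy(model, mask_patterns(X, idx), labels).mean_accuracy
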