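"""End-to-end identification experiment on a synthetic dataset.

Convenience driver tying the modules together: generate a dataset, build
stride patterns per day split, train the network on day 1, evaluate day 2,
run layer-wise relevance propagation on the correct day-2 assignments,
aggregate, rank, and compute the ablation curve and channel-subset
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS
from .classifier import (
    AccuracyReport,
    NetworkModel,
    TrainConfig,
    participant_accuracy,
    predict,
    train,
)
from .preprocessing import PipelineConfig, build_stride_patterns, patterns_matrix
from .reduction import (
    DEFAULT_K_GRID,
    AccuracyCurve,
    ablation_curve,
    channel_subset_accuracy,
)
from .relevance import AggregatedRelevance, aggregate, collect_relevance
from .synthetic import GaitDataset, SyntheticSpec, generate_dataset


@dataclass
class ExperimentResult:
    dataset: GaitDataset
    model: NetworkModel
    report: AccuracyReport  # day-2 evaluation
    aggregated: AggregatedRelevance
    curve: AccuracyCurve
    planted_channel_accuracy: float
    nonplanted_channel_accuracy: float
    X_train: np.ndarray = field(repr=False)
    y_train: np.ndarray = field(repr=False)
    X_test: np.ndarray = field(repr=False)
    y_test: np.ndarray = field(repr=False)


def run_experiment(
    spec: SyntheticSpec,
    train_config: TrainConfig | None = None,
    pipeline_config: PipelineConfig = PipelineConfig(),
    train_seed: int | None = None,
    shuffle_labels: bool = False,
    k_grid=DEFAULT_K_GRID,
) -> ExperimentResult:
    """Run the full analysis once.

    ``shuffle_labels=True`` permutes the day-1 training labels (the
    permutation-null control); ``train_seed`` defaults to ``spec.seed``.
    """
    if train_config is None:
        train_config = TrainConfig()
    if train_seed is None:
        train_seed = spec.seed

    dataset = generate_dataset(spec)
    d1 = dataset.day_trials(1)
    d2 = dataset.day_trials(2)
    patterns = build_stride_patterns(
        d1 + d2, spec.kinematic_rate, spec.force_rate, pipeline_config
    )
    X1, y1 = patterns_matrix(patterns[: len(d1)])
    X2, y2 = patterns_matrix(patterns[len(d1) :])

    y_fit = y1
    if shuffle_labels:
        y_fit = np.random.default_rng(train_seed + 17).permutation(y1)
    model = train(X1, y_fit, train_config, seed=train_seed)

    pred, _ = predict(model, X2)
    report = participant_accuracy(pred, y2, classes=model.classes)
    maps = collect_relevance(model, X2, y2)
    agg = aggregate(maps)
    curve = ablation_curve(model, X2, y2, agg, k_grid)
    planted = list(spec.planted_channels)
    nonplanted = [c for c in CHANNELS if c not in planted]
    return ExperimentResult(
        dataset=dataset,
        model=model,
        report=report,
        aggregated=agg,
        curve=curve,
        planted_channel_accuracy=channel_subset_accuracy(model, X2, y2, planted),
        nonplanted_channel_accuracy=channel_subset_accuracy(model, X2, y2, nonplanted),
        X_train=X1,
        y_train=y1,
        X_test=X2,
        y_test=y2,
    )
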