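"""Layer-wise relevance propagation (LRP) and the group-level aggregation.

For every correctly classified stride pattern, the predicted class's
pre-softmax output score is decomposed into per-input relevances with the
epsilon-stabilized LRP rule

    R_j = sum_k  (a_j w_jk) / (sum_j' a_j' w_j'k + eps * sign(sum)) * R_k,

applied to both dense layers; the element-wise tanh is relevance-
transparent (relevance passes through unchanged).  Because numerator and
denominator share the same sum, relevance is conserved layer to layer up
to the epsilon stabilizer.

Aggregation follows a fixed recipe: each individual map is normalized to
its own maximum, maps are averaged, the average is rectified (absolute
value), each 100-sample channel is smoothed with the (0.25, 0.5, 0.25)
kernel three times (replicate-edge padding; smoothing never crosses the
concatenation seams between channels), and the result is min-max rescaled
to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .channels import CHANNELS, N_CHANNELS, N_SAMPLES, window_samples
from .classifier import NetworkModel, predict

logger = logging.getLogger(__name__)

#: default epsilon of the stabilized LRP rule
DEFAULT_EPS = 1e-6

SMOOTH_KERNEL = np.array([0.25, 0.5, 0.25])
SMOOTH_PASSES = 3


@dataclass(frozen=True)
class RelevanceMap:
    """Signed per-input relevances of one correctly classified stride."""

    values: np.ndarray  # (1200,)
    target_class: int
    score: float  # pre-softmax output score that was decomposed


@dataclass(frozen=True)
class AggregatedRelevance:
    """Smoothed, rectified, [0, 1]-rescaled group relevance pattern."""

    values: np.ndarray  # (1200,) in [0, 1]
    n_patterns: int


def _stabilized(z: np.ndarray, eps: float) -> np.ndarray:
    if eps == 0.0 and np.any(z == 0.0):
        raise ZeroDivisionError("zero denominator in LRP with eps = 0")
    return z + eps * np.where(z >= 0.0, 1.0, -1.0)


def lrp(
    model: NetworkModel,
    pattern: np.ndarray,
    target_class: int,
    eps: float = DEFAULT_EPS,
    rule: str = "epsilon",
    alpha: float = 2.0,
) -> RelevanceMap:
    """Decompose one output score into input relevances.

    Parameters
    ----------
    target_class : int
        Position of the class in the model's output order (use the
        predicted class of a correctly assigned pattern).
    rule : {"epsilon", "alphabeta"}
        ``"alphabeta"`` splits positive and negative contributions with
        weights alpha / (alpha - 1); available for sensitivity analysis.
    """
    x = np.asarray(pattern, dtype=float).ravel()
    if x.size != model.n_features:
        raise ValueError(f"pattern length {x.size} != model input {model.n_features}")
    if not 0 <= target_class < model.n_classes:
        raise IndexError(f"target_class {target_class} out of range")

    a1 = np.tanh(x @ model.W1 + model.b1)
    z2 = a1 @ model.W2 + model.b2
    score = float(z2[target_class])

    if rule == "epsilon":
        # output layer -> hidden: single target unit k
        contrib2 = a1 * model.W2[:, target_class]  # a_j w_jk
        R_hidden = contrib2 / _stabilized(contrib2.sum(), eps) * score
        # tanh is relevance-transparent; hidden -> input
        contrib1 = x[:, None] * model.W1  # a_i w_ij
        denom = _stabilized(contrib1.sum(axis=0), eps)
        R_input = contrib1 @ (R_hidden / denom)
    elif rule == "alphabeta":
        beta = alpha - 1.0
        c2 = a1 * model.W2[:, target_class]
        pos, neg = np.clip(c2, 0, None), np.clip(c2, None, 0)
        R_hidden = (
            alpha * pos / _stabilized(pos.sum(), eps)
            - beta * neg / _stabilized(neg.sum(), -eps)
        ) * score
        c1 = x[:, None] * model.W1
        pos, neg = np.clip(c1, 0, None), np.clip(c1, None, 0)
        R_input = pos @ (alpha * R_hidden / _stabilized(pos.sum(axis=0), eps)) - neg @ (
            beta * R_hidden / _stabilized(neg.sum(axis=0), -eps)
        )
    else:
        raise ValueError(f"unknown LRP rule {rule!r}")

    if not np.all(np.isfinite(R_input)):
        raise FloatingPointError("non-finite relevance encountered")
    return RelevanceMap(values=R_input, target_class=target_class, score=score)


def collect_relevance(
    model: NetworkModel,
    patterns: np.ndarray,
    labels: np.ndarray,
    eps: float = DEFAULT_EPS,
) -> list[RelevanceMap]:
    """Relevance maps for every *correctly* classified pattern.

    Misclassified patterns are excluded and counted in the log.  Raises if
    nothing is classified correctly.
    """
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    y = np.asarray(labels)
    pred, _ = predict(model, X)
    correct = pred == y
    n_excluded = int((~correct).sum())
    if not correct.any():
        raise ValueError("no correctly classified patterns: nothing to decompose")
    if n_excluded:
        logger.info(
            "relevance: %d of %d patterns misclassified and excluded",
            n_excluded,
            y.size,
        )
    class_pos = {c: i for i, c in enumerate(model.classes)}
    return [
        lrp(model, X[i], class_pos[pred[i]], eps=eps)
        for i in np.flatnonzero(correct)
    ]


def smooth_channelwise(values: np.ndarray, passes: int = SMOOTH_PASSES) -> np.ndarray:
    """Apply the 3-tap (0.25, 0.5, 0.25) kernel per 100-sample channel.

    Replicate-edge padding; repeated application converges to a Gaussian
    (three passes equal the 7-tap binomial kernel (1,6,15,20,15,6,1)/64 in
    the interior).  Never mixes samples across channel seams.
    """
    v = np.asarray(values, dtype=float).reshape(N_CHANNELS, N_SAMPLES).copy()
    for _ in range(passes):
        padded = np.pad(v, ((0, 0), (1, 1)), mode="edge")
        v = (
            SMOOTH_KERNEL[0] * padded[:, :-2]
            + SMOOTH_KERNEL[1] * padded[:, 1:-1]
            + SMOOTH_KERNEL[2] * padded[:, 2:]
        )
    return v.ravel()


def aggregate(maps: Sequence[RelevanceMap]) -> AggregatedRelevance:
    """Group-level relevance pattern from individual maps.

    Steps, in order: (1) normalize each map to its own maximum absolute
    value; (2) average element-wise across maps; (3) rectify (absolute
    value); (4) smooth each channel three times with the (0.25, 0.5, 0.25)
    kernel; (5) min-max rescale to [0, 1].

    A degenerate all-equal pattern after smoothing (min = max) cannot be
    rescaled; it is returned as all zeros with a warning.
    """
    if len(maps) == 0:
        raise ValueError("need at least one relevance map")
    stacked = np.stack([m.values for m in maps])
    peak = np.max(np.abs(stacked), axis=1, keepdims=True)
    if np.any(peak == 0.0):
        raise ValueError("relevance map with all-zero values cannot be normalized")
    mean = np.mean(stacked / peak, axis=0)
    rect = np.abs(mean)
    if np.all(rect == 0.0):
        raise ValueError("degenerate aggregation: mean relevance is identically zero")
    smooth = smooth_channelwise(rect)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo == 0.0:
        logger.warning("aggregate: constant relevance pattern; min-max rescale degenerate")
        return AggregatedRelevance(values=np.zeros_like(smooth), n_patterns=len(maps))
    return AggregatedRelevance(values=(smooth - lo) / (hi - lo), n_patterns=len(maps))


def save_relevance(
    agg: AggregatedRelevance, path, maps: Sequence[RelevanceMap] | None = None
) -> None:
    """Write the aggregated relevance as a 12 x 100 delimited table.

    Rows are channels, columns stance samples.  With ``maps`` given, the
    per-stride relevance matrix (strides x 1200, signed) is written next
    to it as ``<path stem>_per_stride<suffix>``.
    """
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    grid = agg.values.reshape(N_CHANNELS, N_SAMPLES)
    pd.DataFrame(grid, index=list(CHANNELS)).to_csv(path)
    if maps is not None:
        per = np.stack([m.values for m in maps])
        pd.DataFrame(per).to_csv(
            path.with_name(path.stem + "_per_stride" + path.suffix), index=False
        )


def summarize(agg: AggregatedRelevance) -> dict:
    """Marginal sums of the aggregated relevance pattern.

    Returns per-time-point sums (over the 12 channels), per-channel sums
    (over the 100 samples), and the early/mid/late-stance split
    (0-30 / 30-70 / 70-100% of stance).
    """
    grid = agg.values.reshape(N_CHANNELS, N_SAMPLES)
    time_totals = grid.sum(axis=0)
    channel_totals = {c: float(grid[i].sum()) for i, c in enumerate(CHANNELS)}
    phases = {
        name: float(time_totals[list(window_samples(win))].sum())
        for name, win in (
            ("early", (0.0, 0.3)),
            ("mid", (0.3, 0.7)),
            ("late", (0.7, 1.0)),
        )
    }
    return {
        "time_totals": time_totals,
        "channel_totals": channel_totals,
        "phase_totals": phases,
    }
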