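"""Shallow fully connected network for subject identification.

Architecture: one input, one hidden and one output layer (1200-2400-50 at
study scale; hidden and output sizes shrink with the dataset), hyperbolic
tangent on the hidden layer, linear outputs trained under softmax
cross-entropy.  Training is plain seeded mini-batch gradient descent
(batch size 25, epoch limit 3000 by default); the only default stopping
rules are the epoch limit and a training-loss plateau tolerance.  The
network is trained on all day-1 stride patterns and evaluated on day-2
patterns with the participant-wise accuracy

    Accuracy(p) = n_p / N_p * 100,

where n_p counts the correctly assigned stride patterns of participant p
and N_p all of that participant's patterns; the overall score is the
unweighted mean across participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (declared package defaults).

    The learning rate, optimizer, initialization and loss are package
    choices.  ``optimizer="momentum"`` (classical momentum 0.9) is the
    default because plain gradient descent needs many more epochs on the
    fluctuation-structure signal the stride patterns carry; ``"sgd"``
    gives plain fixed-rate gradient descent.

    ``init="spectral"`` initializes part of the hidden layer with
    antisymmetric pairs of the training data's principal directions (plus
    a positive bias, so each pair computes an even function of the
    projection).  Per-participant standardization removes all first-order
    (class-mean) identity information from stride patterns, leaving
    identity in the second-order fluctuation structure; gradient descent
    from a generic random initialization sits on a saddle for exactly that
    structure, while the label-free spectral start puts the projections the
    network needs inside its feature layer from epoch 0.
    ``init="uniform"`` gives the plain symmetric fan-in-scaled start.
    """

    batch_size: int = 25
    max_epochs: int = 3000
    learning_rate: float = 0.02
    optimizer: Literal["sgd", "momentum"] = "momentum"
    momentum: float = 0.9
    weight_decay: float = 1e-2
    hidden_size: int | None = None  # None: 2 * n_features, capped at 2400
    init: Literal["spectral", "uniform"] = "spectral"
    init_scale: float = 1.0  # multiplies the +-sqrt(1/fan_in) init range
    n_components: int | None = None  # spectral pairs; None: 24 + n_classes
    spectral_gain: float = 1.2  # tanh pre-activation SD on a principal direction
    spectral_bias: float = 0.6
    loss_tol: float = 1e-6  # stop when the epoch loss improves less than this
    patience: int = 50


@dataclass
class NetworkModel:
    """Weights/biases of the tanh network plus training metadata."""

    W1: np.ndarray  # (n_features, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, n_classes)
    b2: np.ndarray  # (n_classes,)
    classes: np.ndarray  # class labels in output order
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    @property
    def n_classes(self) -> int:
        return self.W2.shape[1]

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1 + self.b1)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Pre-softmax output scores, shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"pattern length {X.shape[1]} != model input size {self.n_features}"
            )
        return self.hidden_activations(X) @ self.W2 + self.b2

    def save(self, path) -> None:
        np.savez(
            path,
            W1=self.W1,
            b1=self.b1,
            W2=self.W2,
            b2=self.b2,
            classes=self.classes,
            meta=np.array([repr(self.training_meta)]),
        )

    @classmethod
    def load(cls, path) -> "NetworkModel":
        import ast

        z = np.load(path, allow_pickle=False)
        return cls(
            W1=z["W1"],
            b1=z["b1"],
            W2=z["W2"],
            b2=z["b2"],
            classes=z["classes"],
            training_meta=ast.literal_eval(str(z["meta"][0])),
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Participant-wise and overall accuracy plus confusion counts."""

    n_correct: dict[int, int]  # participant -> n_p
    n_total: dict[int, int]  # participant -> N_p
    confusion: np.ndarray  # (n_classes, n_classes), rows = true
    classes: np.ndarray

    @property
    def per_participant(self) -> dict[int, float]:
        """Accuracy(p) = n_p / N_p * 100 for every participant with N_p > 0."""
        return {p: 100.0 * self.n_correct[p] / n for p, n in self.n_total.items()}

    @property
    def mean_accuracy(self) -> float:
        """Unweighted mean over participants (each counts once)."""
        per = self.per_participant
        return float(np.mean(list(per.values())))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(
    patterns: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> NetworkModel:
    """Train the shallow tanh network on day-1 stride patterns.

    Mini-batch gradient descent under softmax cross-entropy with per-epoch
    seeded shuffling; fully deterministic given ``seed``.  Weights are
    initialized uniformly in +-sqrt(1/fan_in).

    Raises
    ------
    ValueError
        For fewer than 2 classes, and on a non-finite training loss.
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("patterns must be (n_trials, n_features) aligned with labels")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    n, d = X.shape
    C = classes.size
    H = config.hidden_size if config.hidden_size is not None else min(2 * d, 2400)

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1.0, 1.0, size=(d, H)) * (config.init_scale * np.sqrt(1.0 / d))
    b1 = np.zeros(H)
    W2 = rng.uniform(-1.0, 1.0, size=(H, C)) * (config.init_scale * np.sqrt(1.0 / H))
    b2 = np.zeros(C)
    if config.init == "spectral":
        n_pc = config.n_components if config.n_components is not None else 24 + C
        n_pc = min(n_pc, H // 2, n - 1, d)
        _, S, Vt = np.linalg.svd(X, full_matrices=False)
        lam = S**2 / n
        for k in range(n_pc):
            if lam[k] <= 1e-12:
                break
            v = config.spectral_gain / np.sqrt(lam[k]) * Vt[k]
            W1[:, 2 * k] = v
            W1[:, 2 * k + 1] = -v
            b1[2 * k] = b1[2 * k + 1] = config.spectral_bias
    elif config.init != "uniform":
        raise ValueError(f"unknown init {config.init!r}")
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    Y = np.eye(C)[y_idx]

    lr = config.learning_rate
    mu = config.momentum if config.optimizer == "momentum" else 0.0
    best_loss = np.inf
    stall = 0
    epochs_run = 0
    loss = np.nan
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            a1 = np.tanh(xb @ W1 + b1)
            z2 = a1 @ W2 + b2
            p = _softmax(z2)
            delta2 = (p - yb) / len(idx)
            delta1 = (delta2 @ W2.T) * (1.0 - a1**2)
            gW2 = a1.T @ delta2 + config.weight_decay * W2
            gb2 = delta2.sum(axis=0)
            gW1 = xb.T @ delta1 + config.weight_decay * W1
            gb1 = delta1.sum(axis=0)
            vW2 = mu * vW2 - lr * gW2
            vb2 = mu * vb2 - lr * gb2
            vW1 = mu * vW1 - lr * gW1
            vb1 = mu * vb1 - lr * gb1
            W2 += vW2
            b2 += vb2
            W1 += vW1
            b1 += vb1
        z = np.tanh(X @ W1 + b1) @ W2 + b2
        zs = z - z.max(axis=1, keepdims=True)
        loss = float(
            np.mean(np.log(np.exp(zs).sum(axis=1)) - zs[np.arange(n), y_idx])
        )
        if not np.isfinite(loss):
            raise ValueError(f"training diverged: non-finite loss at epoch {epoch}")
        epochs_run = epoch + 1
        if best_loss - loss < config.loss_tol:
            stall += 1
            if stall >= config.patience:
                logger.info("early stop at epoch %d (loss plateau %.3e)", epoch, loss)
                break
        else:
            stall = 0
        best_loss = min(best_loss, loss)

    return NetworkModel(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        classes=classes,
        training_meta={
            "seed": seed,
            "epochs_run": epochs_run,
            "batch_size": config.batch_size,
            "learning_rate": lr,
            "optimizer": config.optimizer,
            "momentum": mu,
            "hidden_size": H,
            "final_loss": loss,
        },
    )


def predict(model: NetworkModel, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class labels and pre-softmax score vectors.

    The label is the argmax of the output scores; ties break to the lowest
    class index (numpy argmax convention), which makes the untrained
    zero-bias symmetric case deterministic.
    """
    scores = model.scores(patterns)
    labels = model.classes[np.argmax(scores, axis=1)]
    return labels, scores


def participant_accuracy(
    predictions: np.ndarray, labels: np.ndarray, classes: Sequence | None = None
) -> AccuracyReport:
    """Participant-wise accuracy, Accuracy(p) = n_p / N_p * 100.

    The overall ``mean_accuracy`` is the unweighted mean across
    participants (each participant counts once regardless of trial count).
    Participants absent from ``labels`` are excluded and logged.
    """
    pred = np.asarray(predictions)
    true = np.asarray(labels)
    if pred.shape != true.shape:
        raise ValueError("predictions and labels must be aligned")
    cls = np.unique(np.concatenate([true, pred]) if classes is None else np.asarray(classes))
    index = {c: i for i, c in enumerate(cls)}
    confusion = np.zeros((cls.size, cls.size), dtype=int)
    for t, p in zip(true, pred):
        confusion[index[t], index[p]] += 1
    n_total = {c: int(confusion[index[c]].sum()) for c in cls}
    absent = [c for c in cls if n_total[c] == 0]
    if absent:
        logger.info("participants with no trials excluded from accuracy: %s", absent)
    n_total = {c: n for c, n in n_total.items() if n > 0}
    n_correct = {c: int(confusion[index[c], index[c]]) for c in n_total}
    return AccuracyReport(
        n_correct=n_correct, n_total=n_total, confusion=confusion, classes=cls
    )
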