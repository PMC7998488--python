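"""Transductive training and evaluation.

The whole graph is forwarded every epoch; the negative log-likelihood over
the training nodes drives Adam, validation accuracy drives early stopping,
and the best-validation parameters are returned.  All randomness flows from
explicit seeds, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten
from sklearn.metrics import confusion_matrix

from .errors import ConfigError, TrainingDivergedError, ValidationError
from .ggat_core import ModelConfig, default_model_config, ggat_forward, init_params
from .graph_builder import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "SplitIndices",
    "TrainConfig",
    "Metrics",
    "split_nodes",
    "nll_loss",
    "train",
    "evaluate",
]


@dataclass
class SplitIndices:
    """Disjoint train/validation/test node-index sets covering all nodes."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.train, self.validation, self.test)]
        self.train, self.validation, self.test = parts
        allidx = np.concatenate(parts)
        if len(set(allidx.tolist())) != allidx.size:
            raise ValidationError("split indices overlap")


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the reference configuration
    (learning rate 0.005, 8 hidden units, 8 attention heads, 3 layers)."""

    learning_rate: float = 0.005
    hidden_units: int = 8
    heads: int = 8
    n_layers: int = 3
    max_epochs: int = 1000
    patience: int = 100
    seed: int = 0
    activation: str = "softmax"
    interlayer: str = "elu"

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.hidden_units, self.heads, self.n_layers,
               self.max_epochs, self.patience) <= 0:
            raise ConfigError("TrainConfig values must be positive")


@dataclass
class Metrics:
    """Accuracy (and, for binary tasks, sensitivity/specificity) in percent."""

    accuracy: float
    confusion: np.ndarray
    sensitivity: float | None = None
    specificity: float | None = None

    def as_dict(self) -> dict:
        d = {"accuracy": float(self.accuracy)}
        if self.sensitivity is not None:
            d["sensitivity"] = float(self.sensitivity)
            d["specificity"] = float(self.specificity)
        return d


def split_nodes(
    n: int, fractions: tuple[float, float, float] = (0.4, 0.4, 0.2), seed: int = 0
) -> SplitIndices:
    """Seeded shuffle, then contiguous train/validation/test assignment.

    Validation and test sizes are rounded; training takes the remainder.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fractions}")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) <= 0:
        raise ConfigError(f"a split would be empty for n={n}, fractions={fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
    )


def nll_loss(logp, y: np.ndarray, idx: np.ndarray):
    """Mean negative log-likelihood of the true classes over ``idx``.

    Autograd-traceable: ``logp`` may be a boxed array during training.
    """
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValidationError("nll_loss over an empty index set")
    y = np.asarray(y, dtype=int)
    return -logp[idx, y[idx]].sum() / idx.size


def _accuracy(logp: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    pred = np.argmax(logp[idx], axis=1)
    return float(np.mean(pred == y[idx]))


def train(
    G: Graph,
    y: np.ndarray,
    splits: SplitIndices,
    cfg: TrainConfig,
    config: ModelConfig | None = None,
) -> tuple[dict, ModelConfig, dict]:
    """Full-graph Adam training with early stopping on validation accuracy.

    Returns ``(params, model_config, history)`` where ``params`` are the
    best-validation parameters and ``history`` holds per-epoch train loss,
    validation loss/accuracy and the best-so-far validation loss.
    """
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    if n_classes < 2:
        raise ConfigError("training needs at least two classes")
    if config is None:
        config = default_model_config(
            n_classes, cfg.hidden_units, cfg.heads, cfg.n_layers,
            activation=cfg.activation, interlayer=cfg.interlayer,
        )
    params = init_params(config, G.features.shape[1], seed=cfg.seed)
    flat, unflatten = flatten(params)

    X, A = G.features, G.adjacency

    def objective(theta):
        logp = ggat_forward(X, A, unflatten(theta), config)
        return nll_loss(logp, y, splits.train)

    grad_fn = value_and_grad(objective)

    # Adam state
    lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)

    history: dict = {"train_loss": [], "val_loss": [], "val_acc": [], "best_val_loss": []}
    best_acc, best_loss, best_flat, since_improve = -1.0, np.inf, flat.copy(), 0
    min_val_loss = np.inf  # running minimum, recorded in the history

    for epoch in range(1, cfg.max_epochs + 1):
        loss, g = grad_fn(flat)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite training loss at epoch {epoch}")
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        m_hat = m / (1 - b1**epoch)
        v_hat = v / (1 - b2**epoch)
        flat = flat - lr * m_hat / (np.sqrt(v_hat) + eps)

        logp = ggat_forward(X, A, unflatten(flat), config)
        val_loss = float(nll_loss(logp, y, splits.validation))
        val_acc = _accuracy(logp, y, splits.validation)
        history["train_loss"].append(float(loss))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        # patience tracks accuracy plateaus; at equal accuracy the lower-loss
        # parameters are still retained as the best model
        if val_acc > best_acc:
            best_acc, best_loss, best_flat, since_improve = val_acc, val_loss, flat.copy(), 0
        else:
            if val_acc == best_acc and val_loss < best_loss:
                best_loss, best_flat = val_loss, flat.copy()
            since_improve += 1
        min_val_loss = min(min_val_loss, val_loss)
        history["best_val_loss"].append(min_val_loss)
        if since_improve >= cfg.patience:
            logger.info("early stop at epoch %d (best val acc %.3f)", epoch, best_acc)
            break

    return unflatten(best_flat), config, history


def evaluate(
    logp: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    positive_class: int | None = 1,
) -> Metrics:
    """Argmax metrics over ``idx``; TPR/TNR only for binary labels.

    ``positive_class`` names the class treated as positive for sensitivity
    (by convention the cancer label).
    """
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValidationError("evaluate over an empty index set")
    y = np.asarray(y, dtype=int)
    pred = np.argmax(np.asarray(logp)[idx], axis=1)
    truth = y[idx]
    n_classes = int(max(truth.max(), pred.max())) + 1
    conf = confusion_matrix(truth, pred, labels=list(range(n_classes)))
    acc = 100.0 * np.trace(conf) / conf.sum()
    sens = spec = None
    if n_classes == 2 and positive_class is not None:
        pos = int(positive_class)
        neg = 1 - pos
        tp, fn = conf[pos, pos], conf[pos, neg]
        tn, fp = conf[neg, neg], conf[neg, pos]
        sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return Metrics(accuracy=float(acc), confusion=conf, sensitivity=sens, specificity=spec)
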