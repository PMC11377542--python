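"""Target-specific binder/non-binder surrogate and labelling machinery.

Each screening iteration converts docked affinities into binary labels using
a percentile cutoff on the *test* set — binders are compounds with
``dG <= dG_cutoff`` — and trains a fingerprint-based feed-forward classifier
on the accumulated docked set.  The cutoff percentile follows a ten-point
log-spaced schedule from 10% down to 0.01%, so labels get sparser (and the
notion of "binder" stricter) as the campaign focuses.

The classifier takes a 1024-bit Morgan fingerprint and outputs the
probability of the compound being a binder: two dense hidden layers (default
3000 nodes each) with batch normalization and dropout 0.5, then a linear
layer and a sigmoid.  Training minimizes cross-entropy with Adam, monitors
test-set loss every epoch and early-stops; inverse-frequency class weights
compensate for the extreme label imbalance of late iterations.  Everything is
seeded, so a (data, config, seed) triple reproduces the final weights
bit-for-bit on CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


class SurrogateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cutoff schedule and labelling
# ---------------------------------------------------------------------------

def schedule_percent(
    iteration: int, n_points: int = 10, start: float = 10.0, end: float = 0.01
) -> float:
    """Top-N% cutoff percentile for ``iteration`` on a log-spaced schedule.

    Ten points from 10% down to 0.01% by default: iteration 1 -> 10%,
    iteration 2 -> 4.6416%, iteration 10 -> 0.01%.  Endpoints are exact.
    """
    if not 1 <= iteration <= n_points:
        raise SurrogateError(f"iteration {iteration} outside [1, {n_points}]")
    if not start > end > 0:
        raise SurrogateError("need start > end > 0")
    if iteration == 1:
        return float(start)
    if iteration == n_points:
        return float(end)
    log_p = math.log10(start) + (iteration - 1) * (
        math.log10(end) - math.log10(start)
    ) / (n_points - 1)
    return float(10.0 ** log_p)


def compute_cutoff(test_dGs: Sequence[float], top_percent: float) -> float:
    """dG threshold such that the top-N% best (lowest) dGs satisfy dG <= cutoff.

    Uses the k-th smallest value with k = ceil(top_percent/100 * n), so at
    least k compounds (more under ties) pass the ``<=`` rule.
    """
    dgs = np.asarray(test_dGs, dtype=float)
    if dgs.size == 0:
        raise SurrogateError("empty dG list")
    if not 0 < top_percent <= 100:
        raise SurrogateError("top_percent must be in (0, 100]")
    k = math.ceil(top_percent / 100.0 * dgs.size)
    return float(np.partition(dgs, k - 1)[k - 1])


def assign_labels(dGs: Sequence[float], cutoff: float) -> np.ndarray:
    """Binder labels: 1 iff dG <= cutoff (boundary compounds are binders)."""
    return (np.asarray(dGs, dtype=float) <= cutoff).astype(np.int8)


# ---------------------------------------------------------------------------
# model configuration and data containers
# ---------------------------------------------------------------------------

@dataclass
class SurrogateConfig:
    input_bits: int = 1024
    hidden_sizes: tuple[int, int] = (3000, 3000)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 1024
    patience: int = 5
    max_epochs: int = 100
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise SurrogateError("dropout must be in [0, 1)")
        if any(h <= 0 for h in self.hidden_sizes):
            raise SurrogateError("hidden sizes must be positive")


@dataclass
class LabeledSet:
    fingerprints: np.ndarray
    labels: np.ndarray
    dG: np.ndarray | None = None
    role: str = "train"

    def __post_init__(self) -> None:
        self.fingerprints = np.asarray(self.fingerprints)
        self.labels = np.asarray(self.labels).astype(np.int8).ravel()
        if self.fingerprints.shape[0] != self.labels.shape[0]:
            raise SurrogateError("fingerprints and labels length mismatch")
        if self.dG is not None:
            self.dG = np.asarray(self.dG, dtype=float).ravel()
            if self.dG.shape[0] != self.labels.shape[0]:
                raise SurrogateError("dG length mismatch")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class TrainingReport:
    test_losses: list[float]
    best_epoch: int
    best_test_loss: float
    final_test_auc: float
    stopped_early: bool


# ---------------------------------------------------------------------------
# the feed-forward network
# ---------------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float64)
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _BatchNorm:
    def __init__(self, n: int):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)

    def forward(self, x, training: bool):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            self._x = x
            self._mu = mu
            self._var = var
            self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            self._xhat = (x - mu) * self._inv_std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + _BN_EPS)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.dgamma = (grad * self._xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        dxhat = grad * self.gamma
        dx = (
            self._inv_std / n
            * (n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))
        )
        return dx

    def params(self):
        return [(self.gamma, "dgamma"), (self.beta, "dbeta")]


class SurrogateModel:
    """Two-hidden-layer sigmoid classifier over fingerprint bit vectors."""

    def __init__(self, config: SurrogateConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h1, h2 = config.hidden_sizes
        self.lin1 = _Linear(config.input_bits, h1, rng)
        self.bn1 = _BatchNorm(h1)
        self.lin2 = _Linear(h1, h2, rng)
        self.bn2 = _BatchNorm(h2)
        self.lin3 = _Linear(h2, 1, rng)
        self._layers = [self.lin1, self.bn1, self.lin2, self.bn2, self.lin3]
        self._adam_state: dict | None = None
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def _forward(self, x, training: bool, rng: np.random.Generator | None = None):
        p = self.config.dropout
        z = self.lin1.forward(x)
        z = self.bn1.forward(z, training)
        self._relu1 = z > 0
        z = np.where(self._relu1, z, 0.0)
        if training and p > 0:
            self._mask1 = (rng.random(z.shape) >= p) / (1.0 - p)
            z = z * self._mask1
        z = self.lin2.forward(z)
        z = self.bn2.forward(z, training)
        self._relu2 = z > 0
        z = np.where(self._relu2, z, 0.0)
        if training and p > 0:
            self._mask2 = (rng.random(z.shape) >= p) / (1.0 - p)
            z = z * self._mask2
        return self.lin3.forward(z).ravel()

    def _backward(self, grad_logits):
        p = self.config.dropout
        g = self.lin3.backward(grad_logits[:, None])
        if p > 0:
            g = g * self._mask2
        g = np.where(self._relu2, g, 0.0)
        g = self.bn2.backward(g)
        g = self.lin2.backward(g)
        if p > 0:
            g = g * self._mask1
        g = np.where(self._relu1, g, 0.0)
        g = self.bn1.backward(g)
        self.lin1.backward(g)

    # -- optimizer ----------------------------------------------------------
    def _adam_step(self):
        cfg = self.config
        if self._adam_state is None:
            self._adam_state = {}
            for li, layer in enumerate(self._layers):
                for pi, (param, _) in enumerate(layer.params()):
                    self._adam_state[(li, pi)] = (
                        np.zeros_like(param),
                        np.zeros_like(param),
                    )
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for li, layer in enumerate(self._layers):
            for pi, (param, gname) in enumerate(layer.params()):
                grad = getattr(layer, gname)
                m, v = self._adam_state[(li, pi)]
                m[:] = b1 * m + (1 - b1) * grad
                v[:] = b2 * v + (1 - b2) * grad ** 2
                mhat = m / (1 - b1 ** t)
                vhat = v / (1 - b2 ** t)
                param -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------
    def predict(self, fingerprints: np.ndarray, chunk_size: int = 8192) -> np.ndarray:
        """Binder probabilities in [0, 1]; independent of chunking."""
        x = np.asarray(fingerprints, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_bits:
            raise SurrogateError(
                f"expected (n, {self.config.input_bits}) fingerprints, got {x.shape}"
            )
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], chunk_size):
            logits = self._forward(x[start : start + chunk_size], training=False)
            out[start : start + chunk_size] = 1.0 / (1.0 + np.exp(-logits))
        return out

    def state_dict(self) -> dict:
        return {
            "W1": self.lin1.W.copy(), "b1": self.lin1.b.copy(),
            "g1": self.bn1.gamma.copy(), "be1": self.bn1.beta.copy(),
            "rm1": self.bn1.running_mean.copy(), "rv1": self.bn1.running_var.copy(),
            "W2": self.lin2.W.copy(), "b2": self.lin2.b.copy(),
            "g2": self.bn2.gamma.copy(), "be2": self.bn2.beta.copy(),
            "rm2": self.bn2.running_mean.copy(), "rv2": self.bn2.running_var.copy(),
            "W3": self.lin3.W.copy(), "b3": self.lin3.b.copy(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.lin1.W, self.lin1.b = state["W1"].copy(), state["b1"].copy()
        self.bn1.gamma, self.bn1.beta = state["g1"].copy(), state["be1"].copy()
        self.bn1.running_mean, self.bn1.running_var = state["rm1"].copy(), state["rv1"].copy()
        self.lin2.W, self.lin2.b = state["W2"].copy(), state["b2"].copy()
        self.bn2.gamma, self.bn2.beta = state["g2"].copy(), state["be2"].copy()
        self.bn2.running_mean, self.bn2.running_var = state["rm2"].copy(), state["rv2"].copy()
        self.lin3.W, self.lin3.b = state["W3"].copy(), state["b3"].copy()


def _bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def train_surrogate(
    train: LabeledSet, test: LabeledSet, config: SurrogateConfig
) -> tuple[SurrogateModel, TrainingReport]:
    """Train the classifier with early stopping on test cross-entropy.

    Requires both classes in the training set.  Returns the model restored to
    its best-epoch weights, plus a report with the per-epoch test losses, the
    selected epoch and the final test AUC.
    """
    y_train = train.labels.astype(np.float64)
    if len(np.unique(y_train)) < 2:
        raise SurrogateError("training set must contain both classes")
    if len(train) == 0 or len(test) == 0:
        raise SurrogateError("empty training or test set")

    model = SurrogateModel(config)
    rng = np.random.default_rng(config.seed + 1)
    x_train = np.asarray(train.fingerprints, dtype=np.float64)
    x_test = np.asarray(test.fingerprints, dtype=np.float64)
    y_test = test.labels.astype(np.float64)

    if config.class_weighting:
        n_pos = y_train.sum()
        n_neg = len(y_train) - n_pos
        w_pos = len(y_train) / (2.0 * n_pos)
        w_neg = len(y_train) / (2.0 * n_neg)
    else:
        w_pos = w_neg = 1.0
    weights = np.where(y_train == 1, w_pos, w_neg)

    best_loss = math.inf
    best_state = model.state_dict()
    best_epoch = 0
    test_losses: list[float] = []
    stale = 0
    stopped_early = False

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(y_train))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batchnorm needs >= 2 rows
            xb, yb, wb = x_train[idx], y_train[idx], weights[idx]
            logits = model._forward(xb, training=True, rng=rng)
            probs = 1.0 / (1.0 + np.exp(-logits))
            grad = wb * (probs - yb) / len(yb)
            model._backward(grad)
            model._adam_step()
        test_probs = model.predict(x_test)
        loss = _bce_loss(test_probs, y_test)
        test_losses.append(loss)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best_state = model.state_dict()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                stopped_early = True
                break

    model.load_state_dict(best_state)
    test_probs = model.predict(x_test)
    if len(np.unique(y_test)) == 2:
        auc = float(roc_auc_score(y_test, test_probs))
    else:
        auc = float("nan")
    report = TrainingReport(
        test_losses=test_losses,
        best_epoch=best_epoch,
        best_test_loss=best_loss,
        final_test_auc=auc,
        stopped_early=stopped_early,
    )
    return model, report


def predict_library(model: SurrogateModel, fingerprints: np.ndarray) -> np.ndarray:
    """Score a fingerprint matrix; thin alias for :meth:`SurrogateModel.predict`."""
    return model.predict(fingerprints)
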