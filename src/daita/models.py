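"""Pluggable small classifiers fulfilling the model contract.

Full-scale pretrained convolutional backbones are out of scope at desk scale;
any classifier that can (a) train for a given number of epochs on local data
under the distillation loss, (b) emit per-sample logit vectors, and (c)
export/import its parameters as a flat vector can ride the decentralized
training machinery.  Two reference implementations are provided: multinomial
softmax regression and a one-hidden-layer MLP, both trained by minibatch
gradient descent with the analytic logit gradient of the distillation loss.
"""

from __future__ import annotations

import abc
from typing import Optional

import numpy as np

from daita.distillation import DistillationConfig, kd_loss, kd_loss_grad, softmax

__all__ = ["ModelContract", "SoftmaxRegression", "TinyMLP", "make_model"]


class ModelContract(abc.ABC):
    """Interface every traveling model must satisfy.

    Invariant: an ``export_weights`` → ``import_weights`` round trip
    reproduces identical predictions, and same-architecture models have
    weight vectors of equal length (required for weight averaging).
    """

    architecture: str = "abstract"
    class_count: int = 2

    @abc.abstractmethod
    def predict_logits(self, inputs: np.ndarray) -> np.ndarray:
        """Per-sample raw logit vectors of shape ``(n, class_count)``."""

    @abc.abstractmethod
    def export_weights(self) -> np.ndarray:
        """All parameters as one flat float vector."""

    @abc.abstractmethod
    def import_weights(self, flat: np.ndarray) -> None:
        """Restore parameters from a flat vector produced by export."""

    @abc.abstractmethod
    def _logit_backward(self, inputs: np.ndarray, grad_logits: np.ndarray) -> np.ndarray:
        """Flat parameter gradient given the loss gradient at the logits."""

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(inputs))

    def clone(self) -> "ModelContract":
        other = type(self)(self.n_features, self.class_count, **self._init_kwargs())
        other.import_weights(self.export_weights())
        return other

    def _init_kwargs(self) -> dict:
        return {}

    def train_epochs(
        self,
        inputs: np.ndarray,
        hard_labels: np.ndarray,
        epochs: int,
        config: DistillationConfig,
        teacher_soft: Optional[np.ndarray] = None,
        rng: Optional[np.random.Generator] = None,
        batch_size: int = 32,
        learning_rate: float = 0.1,
    ) -> list[float]:
        """Minibatch gradient descent on the distillation loss.

        ``teacher_soft`` holds the combined teacher distributions for the full
        local dataset, aligned row-for-row with ``inputs``; it may be None when
        ``config.alpha == 1`` (plain supervised training).  ``rng`` drives the
        per-epoch shuffle; one permutation is drawn per epoch so a caller
        holding the generator can reproduce the exact batch schedule.

        Returns the mean epoch losses.
        """
        x = np.asarray(inputs, dtype=float)
        y = np.asarray(hard_labels)
        if x.shape[0] == 0:
            raise ValueError("cannot train on an empty dataset")
        if rng is None:
            rng = np.random.default_rng()
        n = x.shape[0]
        epoch_losses: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                zb = self.predict_logits(x[idx])
                tb = None if teacher_soft is None else teacher_soft[idx]
                cfg = _slice_sample_weights(config, idx)
                losses.append(kd_loss(zb, y[idx], tb, cfg))
                grad_logits = kd_loss_grad(zb, y[idx], tb, cfg)
                grad_flat = self._logit_backward(x[idx], grad_logits)
                self.import_weights(self.export_weights() - learning_rate * grad_flat)
            epoch_losses.append(float(np.mean(losses)))
        return epoch_losses


def _slice_sample_weights(config: DistillationConfig, idx: np.ndarray) -> DistillationConfig:
    if config.sample_weights is None:
        return config
    sliced = DistillationConfig(
        temperature=config.temperature,
        alpha=config.alpha,
        teacher_weights=config.teacher_weights,
        class_weights=config.class_weights,
        node_weight=config.node_weight,
        sample_weights=np.asarray(config.sample_weights)[idx],
        per_teacher_kl=config.per_teacher_kl,
    )
    return sliced


class SoftmaxRegression(ModelContract):
    """Linear logits ``X W + b`` — fast, convex, fully deterministic."""

    architecture = "softmax_regression"

    def __init__(self, n_features: int, class_count: int = 2, seed: int = 0):
        self.n_features = n_features
        self.class_count = class_count
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, 0.01, size=(n_features, class_count))
        self.b = np.zeros(class_count)

    def predict_logits(self, inputs: np.ndarray) -> np.ndarray:
        return np.asarray(inputs, dtype=float) @ self.W + self.b

    def export_weights(self) -> np.ndarray:
        return np.concatenate([self.W.ravel(), self.b])

    def import_weights(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        expected = self.n_features * self.class_count + self.class_count
        if flat.size != expected:
            raise ValueError(f"expected {expected} weights, got {flat.size}")
        self.W = flat[: self.n_features * self.class_count].reshape(
            self.n_features, self.class_count
        )
        self.b = flat[self.n_features * self.class_count :].copy()

    def _logit_backward(self, inputs: np.ndarray, grad_logits: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs, dtype=float)
        grad_w = x.T @ grad_logits
        grad_b = grad_logits.sum(axis=0)
        return np.concatenate([grad_w.ravel(), grad_b])


class TinyMLP(ModelContract):
    """One tanh hidden layer; enough capacity for non-linear toy images."""

    architecture = "tiny_mlp"

    def __init__(self, n_features: int, class_count: int = 2, hidden: int = 16, seed: int = 0):
        self.n_features = n_features
        self.class_count = class_count
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        scale1 = 1.0 / np.sqrt(n_features)
        scale2 = 1.0 / np.sqrt(hidden)
        self.W1 = rng.normal(0.0, scale1, size=(n_features, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, scale2, size=(hidden, class_count))
        self.b2 = np.zeros(class_count)

    def _init_kwargs(self) -> dict:
        return {"hidden": self.hidden}

    def _hidden_out(self, inputs: np.ndarray) -> np.ndarray:
        return np.tanh(np.asarray(inputs, dtype=float) @ self.W1 + self.b1)

    def predict_logits(self, inputs: np.ndarray) -> np.ndarray:
        return self._hidden_out(inputs) @ self.W2 + self.b2

    def export_weights(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def import_weights(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        sizes = [
            self.n_features * self.hidden,
            self.hidden,
            self.hidden * self.class_count,
            self.class_count,
        ]
        if flat.size != sum(sizes):
            raise ValueError(f"expected {sum(sizes)} weights, got {flat.size}")
        a, b, c, _ = np.cumsum(sizes)
        self.W1 = flat[:a].reshape(self.n_features, self.hidden)
        self.b1 = flat[a:b].copy()
        self.W2 = flat[b:c].reshape(self.hidden, self.class_count)
        self.b2 = flat[c:].copy()

    def _logit_backward(self, inputs: np.ndarray, grad_logits: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs, dtype=float)
        h = self._hidden_out(x)
        grad_w2 = h.T @ grad_logits
        grad_b2 = grad_logits.sum(axis=0)
        grad_h = grad_logits @ self.W2.T
        grad_pre = grad_h * (1.0 - h * h)
        grad_w1 = x.T @ grad_pre
        grad_b1 = grad_pre.sum(axis=0)
        return np.concatenate([grad_w1.ravel(), grad_b1, grad_w2.ravel(), grad_b2])


def make_model(
    architecture: str, n_features: int, class_count: int = 2, seed: int = 0, **kwargs
) -> ModelContract:
    """Factory used by experiment configs; the architecture tag selects."""
    if architecture == "softmax_regression":
        return SoftmaxRegression(n_features, class_count, seed=seed)
    if architecture == "tiny_mlp":
        return TinyMLP(n_features, class_count, seed=seed, **kwargs)
    raise ValueError(f"unknown architecture {architecture!r}")
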