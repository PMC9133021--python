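"""Temperature-softened multi-teacher knowledge distillation.

The student trains against a mixture of two signals: ordinary cross-entropy
on the (possibly noisy) hard labels, and the Kullback–Leibler divergence from
the averaged, temperature-softened teacher distributions to its own softened
outputs.  With temperature ``T`` and mixing weight ``alpha`` the per-sample
objective is the canonical distillation loss

    L_i = alpha * CE(y_i, softmax(z_i))
        + (1 - alpha) * T**2 * KL(q_i || softmax(z_i / T))

where ``z_i`` are the student logits and ``q_i`` the combined teacher
distribution.  The ``T**2`` factor compensates the ``1/T`` shrinkage of the
softened-logit gradients so the distillation term keeps a comparable gradient
scale across temperatures.  Each sample's loss is additionally scaled by a
multiplicative three-level weight: its own sample weight, the class weight of
its hard label, and the weight of the node currently hosting the training.

Class 0 is cat/non-viable, class 1 is dog/viable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DistillationConfig",
    "soften",
    "combine_teachers",
    "kd_loss",
    "kd_loss_grad",
    "ensemble_predict",
    "softmax",
]

#: Floor for probabilities inside logarithms; guards degenerate teachers.
PROB_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for stability."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class DistillationConfig:
    """Knobs of the distillation objective.

    Parameters
    ----------
    temperature
        Softening temperature ``T > 0``; higher flattens teacher and student
        output distributions.
    alpha
        Weight in ``[0, 1]`` on the hard-label cross-entropy term; ``1 - alpha``
        goes to the teacher KL term.  ``alpha=1`` ignores the teachers.
    teacher_weights
        One nonnegative weight per teacher; normalized to sum to 1.  ``None``
        means uniform.
    class_weights
        Positive per-class loss weights.  ``None`` means all ones; see
        :func:`inverse_frequency_class_weights` for the inverse-frequency
        default used in noisy-label experiments.
    node_weight
        Positive weight of the node currently hosting the training.
    sample_weights
        Optional positive per-sample weights (default all ones).
    per_teacher_kl
        If True, average per-teacher KL terms instead of averaging teacher
        distributions before a single KL (sensitivity switch; identical for a
        single teacher).
    """

    temperature: float = 2.0
    alpha: float = 0.5
    teacher_weights: Optional[np.ndarray] = None
    class_weights: Optional[np.ndarray] = None
    node_weight: float = 1.0
    sample_weights: Optional[np.ndarray] = None
    per_teacher_kl: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError("temperature must be a positive finite real")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.node_weight <= 0 or not np.isfinite(self.node_weight):
            raise ValueError("node_weight must be positive and finite")
        if self.teacher_weights is not None:
            w = np.asarray(self.teacher_weights, dtype=float)
            if np.any(w < 0) or not np.all(np.isfinite(w)) or w.sum() <= 0:
                raise ValueError("teacher_weights must be nonnegative with positive sum")
            self.teacher_weights = w / w.sum()
        if self.class_weights is not None:
            cw = np.asarray(self.class_weights, dtype=float)
            if np.any(cw <= 0) or not np.all(np.isfinite(cw)):
                raise ValueError("class_weights must be positive and finite")
            self.class_weights = cw

    def to_dict(self) -> dict:
        return {
            "temperature": self.temperature,
            "alpha": self.alpha,
            "teacher_weights": None
            if self.teacher_weights is None
            else list(map(float, self.teacher_weights)),
            "class_weights": None
            if self.class_weights is None
            else list(map(float, self.class_weights)),
            "node_weight": self.node_weight,
            "per_teacher_kl": self.per_teacher_kl,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistillationConfig":
        d = dict(d)
        for key in ("teacher_weights", "class_weights"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def inverse_frequency_class_weights(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Class weights ``N / (K * N_c)``, computed from the (noisy) labels.

    Upweights the rarer labelled class so asymmetric label flipping does not
    let the majority label dominate the loss.
    """
    labels = np.asarray(labels)
    n = labels.size
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0  # a node missing a class: renormalize over present ones
    return n / (n_classes * counts)


def soften(logits: np.ndarray, temperature: float) -> np.ndarray:
    """Temperature-softened class probabilities, ``softmax(logits / T)``.

    ``T=1`` reproduces the ordinary softmax output; ``T → inf`` flattens every
    row toward the uniform distribution.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    return softmax(logits / temperature)


def combine_teachers(
    teacher_soft: Sequence[np.ndarray],
    teacher_weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Weighted arithmetic mean of teacher soft-label sets.

    All teachers must share sample and class counts; the result is again
    row-stochastic.
    """
    if len(teacher_soft) == 0:
        raise ValueError("need at least one teacher")
    mats = [np.asarray(t, dtype=float) for t in teacher_soft]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("teacher soft-label sets must share shape")
    if teacher_weights is None:
        w = np.full(len(mats), 1.0 / len(mats))
    else:
        w = np.asarray(teacher_weights, dtype=float)
        if w.shape != (len(mats),):
            raise ValueError("one weight per teacher required")
        w = w / w.sum()
    return np.tensordot(w, np.stack(mats), axes=1)


def _three_level_weights(
    hard_labels: np.ndarray, n_classes: int, config: DistillationConfig
) -> np.ndarray:
    n = hard_labels.size
    sw = (
        np.ones(n)
        if config.sample_weights is None
        else np.asarray(config.sample_weights, dtype=float)
    )
    if sw.shape != (n,):
        raise ValueError("sample_weights must match the batch size")
    cw = (
        np.ones(n_classes)
        if config.class_weights is None
        else np.asarray(config.class_weights, dtype=float)
    )
    if cw.size < n_classes:
        raise ValueError("class_weights must cover every class")
    return sw * cw[hard_labels] * config.node_weight


def kd_loss(
    student_logits: np.ndarray,
    hard_labels: np.ndarray,
    combined_teacher_soft: Optional[np.ndarray],
    config: DistillationConfig,
) -> float:
    """Distillation loss: weighted mean of per-sample CE + T²·KL terms.

    Returns ``sum_i w_i * [alpha*CE_i + (1-alpha)*T²*KL_i] / N`` where
    ``w_i`` is the multiplicative sample × class × node weight.  Dividing by
    the batch size ``N`` (not the weight sum) makes ``alpha=1`` with unit
    weights coincide exactly with the plain mean cross-entropy.

    ``combined_teacher_soft`` may be None when ``alpha == 1``.
    """
    z = np.asarray(student_logits, dtype=float)
    y = np.asarray(hard_labels)
    if z.ndim != 2 or z.shape[0] == 0:
        raise ValueError("student_logits must be a nonempty (n, K) array")
    if y.shape != (z.shape[0],):
        raise ValueError("hard_labels must match the batch size")
    n, k = z.shape
    w = _three_level_weights(y, k, config)

    p = softmax(z)
    ce = -np.log(np.clip(p[np.arange(n), y], PROB_EPS, 1.0))
    terms = config.alpha * ce

    if config.alpha < 1.0:
        if combined_teacher_soft is None:
            raise ValueError("teacher soft labels required when alpha < 1")
        q = np.asarray(combined_teacher_soft, dtype=float)
        if q.shape != z.shape:
            raise ValueError("teacher soft labels must match student logits shape")
        t = config.temperature
        p_t = np.clip(softmax(z / t), PROB_EPS, 1.0)
        q_c = np.clip(q, PROB_EPS, 1.0)
        kl = np.sum(q_c * (np.log(q_c) - np.log(p_t)), axis=1)
        terms = terms + (1.0 - config.alpha) * t * t * kl

    return float(np.sum(w * terms) / n)


def kd_loss_grad(
    student_logits: np.ndarray,
    hard_labels: np.ndarray,
    combined_teacher_soft: Optional[np.ndarray],
    config: DistillationConfig,
) -> np.ndarray:
    """Analytic gradient of :func:`kd_loss` w.r.t. the student logits.

    CE term: ``alpha * w * (p - onehot) / N``.  KL term with teacher
    distribution ``q``: ``(1-alpha) * T² * w * (p_T - q) / (T * N)``
    (clamping ignored, as is standard).
    """
    z = np.asarray(student_logits, dtype=float)
    y = np.asarray(hard_labels)
    n, k = z.shape
    w = _three_level_weights(y, k, config)[:, None]

    p = softmax(z)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    grad = config.alpha * w * (p - onehot)

    if config.alpha < 1.0:
        q = np.asarray(combined_teacher_soft, dtype=float)
        t = config.temperature
        p_t = softmax(z / t)
        grad = grad + (1.0 - config.alpha) * t * w * (p_t - q)

    return grad / n


def ensemble_predict(models: Sequence, inputs: np.ndarray) -> np.ndarray:
    """Unweighted mean of member probability outputs (no distillation).

    The non-distilled alternative: ensemble all trained generalists directly.
    """
    if len(models) == 0:
        raise ValueError("need at least one model")
    probs = [softmax(m.predict_logits(inputs)) for m in models]
    shape = probs[0].shape
    if any(p.shape != shape for p in probs):
        raise ValueError("all members must share the class count")
    return np.mean(np.stack(probs), axis=0)
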