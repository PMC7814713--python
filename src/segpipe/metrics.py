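"""Segmentation losses and evaluation metrics.

All functions take the ground truth as a one-hot array and the prediction
as per-class probabilities, both with the class axis last, and reduce over
every voxel (and, for batched input, every batch member).  Smoothing with a
small ``eps`` (default 1e-5) keeps the ratios defined on empty classes; a
class absent from both truth and prediction therefore scores eps/eps = 1,
which inflates class-wise means when classes are missing and is documented
as the absent-class convention.

The Tversky index generalizes Dice with separate false-positive (alpha) and
false-negative (beta) weights over soft counts:

    TI_c = (sum t_c p_c + eps/2) /
           (sum t_c p_c + alpha sum (1-t_c) p_c + beta sum t_c (1-p_c) + eps/2)

and the Tversky loss is ``1 - mean_c TI_c``.  In the Tversky and Jaccard
ratios the smoothing enters halved, which makes two algebraic identities
hold exactly rather than asymptotically: alpha = beta = 0.5 reduces the
Tversky index to the class-wise soft Dice smoothed with ``eps``, and the
Jaccard index satisfies J = D / (2 - D).  Defaults alpha=0.3,
beta=0.7 weight recall over precision for unbalanced foregrounds.

Metrics registered here (built-ins plus user metrics via
:func:`register_metric`) are resolvable by name from the pipeline config,
both as the training loss — when an analytic gradient with respect to the
predicted probabilities is available — and for evaluation reporting.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, ValidationError

DEFAULT_EPS = 1e-5


@dataclasses.dataclass(frozen=True)
class TverskyParams:
    """False-positive weight alpha, false-negative weight beta, smoothing eps."""

    alpha: float = 0.3
    beta: float = 0.7
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be >= 0")
        if self.alpha + self.beta <= 0:
            raise ValidationError("alpha + beta must be > 0")
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/FP/FN/TN voxel counts for hard label masks."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray


def confusion_counts(truth_labels: np.ndarray, pred_labels: np.ndarray,
                     n_classes: int) -> ConfusionCounts:
    """Count per-class TP/FP/FN/TN between two integer label masks."""
    if truth_labels.shape != pred_labels.shape:
        raise ValidationError("label masks must have equal shapes")
    total = truth_labels.size
    tp = np.empty(n_classes, dtype=np.int64)
    fp = np.empty(n_classes, dtype=np.int64)
    fn = np.empty(n_classes, dtype=np.int64)
    for c in range(n_classes):
        t = truth_labels == c
        p = pred_labels == c
        tp[c] = np.count_nonzero(t & p)
        fp[c] = np.count_nonzero(~t & p)
        fn[c] = np.count_nonzero(t & ~p)
    return ConfusionCounts(tp, fp, fn, total - tp - fp - fn)


def _check_shapes(truth: np.ndarray, pred: np.ndarray) -> None:
    if truth.shape != pred.shape:
        raise ValidationError(
            f"truth shape {truth.shape} != prediction shape {pred.shape}"
        )
    if truth.ndim < 2:
        raise ValidationError("arrays need at least one spatial axis plus the class axis")


def _class_sums(truth: np.ndarray, pred: np.ndarray
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = tuple(range(truth.ndim - 1))
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    return (t * p).sum(axis=axes), t.sum(axis=axes), p.sum(axis=axes)


def soft_dice(truth_onehot: np.ndarray, pred_prob: np.ndarray,
              eps: float = DEFAULT_EPS) -> float:
    """Global soft Dice: all voxels and classes pooled into one ratio."""
    _check_shapes(truth_onehot, pred_prob)
    inter, t_sum, p_sum = _class_sums(truth_onehot, pred_prob)
    return float((2.0 * inter.sum() + eps) / (t_sum.sum() + p_sum.sum() + eps))


def classwise_dice(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                   eps: float = DEFAULT_EPS) -> Tuple[np.ndarray, float]:
    """Per-class soft Dice scores and their unweighted mean."""
    _check_shapes(truth_onehot, pred_prob)
    inter, t_sum, p_sum = _class_sums(truth_onehot, pred_prob)
    scores = (2.0 * inter + eps) / (t_sum + p_sum + eps)
    return scores, float(scores.mean())


def jaccard_index(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                  eps: float = DEFAULT_EPS) -> float:
    """Global soft Jaccard (intersection over union)."""
    _check_shapes(truth_onehot, pred_prob)
    inter, t_sum, p_sum = _class_sums(truth_onehot, pred_prob)
    i, t, p = inter.sum(), t_sum.sum(), p_sum.sum()
    # eps/2 smoothing keeps J = D / (2 - D) an exact identity (see module doc)
    return float((i + 0.5 * eps) / (t + p - i + 0.5 * eps))


def classwise_jaccard(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                      eps: float = DEFAULT_EPS) -> Tuple[np.ndarray, float]:
    """Per-class soft Jaccard scores and their unweighted mean."""
    _check_shapes(truth_onehot, pred_prob)
    inter, t_sum, p_sum = _class_sums(truth_onehot, pred_prob)
    scores = (inter + 0.5 * eps) / (t_sum + p_sum - inter + 0.5 * eps)
    return scores, float(scores.mean())


def tversky_index(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                  params: TverskyParams = TverskyParams()) -> np.ndarray:
    """Per-class Tversky index over soft counts."""
    _check_shapes(truth_onehot, pred_prob)
    axes = tuple(range(truth_onehot.ndim - 1))
    t = np.asarray(truth_onehot, dtype=np.float64)
    p = np.asarray(pred_prob, dtype=np.float64)
    tp = (t * p).sum(axis=axes)
    fp = ((1.0 - t) * p).sum(axis=axes)
    fn = (t * (1.0 - p)).sum(axis=axes)
    # smoothing enters as eps/2 so that alpha = beta = 0.5 reduces exactly to
    # the class-wise soft Dice with smoothing eps (an algebraic identity)
    half = 0.5 * params.eps
    return (tp + half) / (tp + params.alpha * fp + params.beta * fn + half)


def tversky_loss(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                 params: TverskyParams = TverskyParams()) -> float:
    """1 minus the class-mean Tversky index; the default training loss."""
    return float(1.0 - tversky_index(truth_onehot, pred_prob, params).mean())


def tversky_training_loss(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                          params: TverskyParams = TverskyParams()) -> float:
    """Tversky loss averaged over the classes present in the ground truth.

    Used as the training objective.  With small patches and batches, rare
    classes are absent from most batches; including their smoothed ratio in
    the class mean rewards driving the class probability to exactly zero
    (the ratio jumps from ~0 to eps/eps = 1), a degenerate optimum from
    which a saturated softmax cannot recover.  Restricting the mean to
    present classes removes that incentive; the evaluation metric
    :func:`tversky_loss` keeps the plain all-class mean.
    """
    _check_shapes(truth_onehot, pred_prob)
    axes = tuple(range(truth_onehot.ndim - 1))
    present = np.asarray(truth_onehot, dtype=bool).any(axis=axes)
    ti = tversky_index(truth_onehot, pred_prob, params)
    return float(1.0 - ti[present].mean())


def tversky_training_loss_grad(truth: np.ndarray, pred: np.ndarray,
                               params: TverskyParams = TverskyParams()
                               ) -> np.ndarray:
    axes = tuple(range(truth.ndim - 1))
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    present = t.any(axis=axes)
    tp = (t * p).sum(axis=axes)
    fp = ((1.0 - t) * p).sum(axis=axes)
    fn = (t * (1.0 - p)).sum(axis=axes)
    half = 0.5 * params.eps
    num = tp + half
    den = tp + params.alpha * fp + params.beta * fn + half
    dden = t + params.alpha * (1.0 - t) - params.beta * t
    dTI = (t * den - num * dden) / den ** 2
    dTI[..., ~present] = 0.0
    return -dTI / max(1, int(present.sum()))


def categorical_crossentropy(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                             clip: float = 1e-7) -> float:
    """Mean per-voxel cross-entropy, probabilities clipped into (0, 1)."""
    _check_shapes(truth_onehot, pred_prob)
    p = np.clip(np.asarray(pred_prob, dtype=np.float64), clip, 1.0 - clip)
    n_voxels = int(np.prod(truth_onehot.shape[:-1]))
    return float(-(truth_onehot * np.log(p)).sum() / n_voxels)


def crossentropy_dice(truth_onehot: np.ndarray, pred_prob: np.ndarray,
                      eps: float = DEFAULT_EPS) -> float:
    """Combined score CE - soft Dice; negative when the prediction is good."""
    return (categorical_crossentropy(truth_onehot, pred_prob)
            - soft_dice(truth_onehot, pred_prob, eps))


# ----------------------------------------------------------- loss gradients
# Analytic gradients with respect to pred_prob, needed because the bundled
# network backend trains by explicit backpropagation.

def _soft_dice_grad(truth: np.ndarray, pred: np.ndarray,
                    eps: float = DEFAULT_EPS) -> np.ndarray:
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    inter = (t * p).sum()
    denom = t.sum() + p.sum() + eps
    num = 2.0 * inter + eps
    return (2.0 * t * denom - num) / denom ** 2


def soft_dice_loss_grad(truth: np.ndarray, pred: np.ndarray,
                        eps: float = DEFAULT_EPS) -> np.ndarray:
    return -_soft_dice_grad(truth, pred, eps)


def tversky_loss_grad(truth: np.ndarray, pred: np.ndarray,
                      params: TverskyParams = TverskyParams()) -> np.ndarray:
    axes = tuple(range(truth.ndim - 1))
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    tp = (t * p).sum(axis=axes)
    fp = ((1.0 - t) * p).sum(axis=axes)
    fn = (t * (1.0 - p)).sum(axis=axes)
    half = 0.5 * params.eps
    num = tp + half
    den = tp + params.alpha * fp + params.beta * fn + half
    # d num / d p_v = t_v ; d den / d p_v = t_v + alpha (1 - t_v) - beta t_v
    dden = t + params.alpha * (1.0 - t) - params.beta * t
    n_classes = truth.shape[-1]
    dTI = (t * den - num * dden) / den ** 2
    return -dTI / n_classes


def crossentropy_grad(truth: np.ndarray, pred: np.ndarray,
                      clip: float = 1e-7) -> np.ndarray:
    p = np.clip(np.asarray(pred, dtype=np.float64), clip, 1.0 - clip)
    n_voxels = int(np.prod(truth.shape[:-1]))
    grad = -np.asarray(truth, dtype=np.float64) / p / n_voxels
    return np.where((pred > clip) & (pred < 1.0 - clip), grad, 0.0)


def crossentropy_dice_grad(truth: np.ndarray, pred: np.ndarray,
                           eps: float = DEFAULT_EPS) -> np.ndarray:
    return crossentropy_grad(truth, pred) - _soft_dice_grad(truth, pred, eps)


# ----------------------------------------------------------------- registry

MetricFn = Callable[[np.ndarray, np.ndarray], float]
GradFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclasses.dataclass(frozen=True)
class Metric:
    """A named metric: evaluation value, plus optional trainable-loss pair."""

    name: str
    fn: MetricFn
    loss_fn: Optional[MetricFn] = None
    loss_grad: Optional[GradFn] = None


_METRIC_REGISTRY: Dict[str, Metric] = {}


def register_metric(name: str, fn: MetricFn, loss_fn: Optional[MetricFn] = None,
                    loss_grad: Optional[GradFn] = None) -> None:
    """Register a metric under a config-resolvable name.

    Supplying ``loss_fn`` and ``loss_grad`` (gradient with respect to the
    predicted probabilities) additionally makes the metric usable as a
    training loss.
    """
    if name in _METRIC_REGISTRY:
        raise ConfigurationError(f"metric {name!r} is already registered")
    if not callable(fn):
        raise ValidationError("metric fn must be callable")
    _METRIC_REGISTRY[name] = Metric(name, fn, loss_fn, loss_grad)


def get_metric(name: str) -> Metric:
    if name not in _METRIC_REGISTRY:
        raise ConfigurationError(
            f"unknown metric {name!r}; registered: {sorted(_METRIC_REGISTRY)}"
        )
    return _METRIC_REGISTRY[name]


def get_loss(name: str) -> Tuple[MetricFn, GradFn]:
    metric = get_metric(name)
    if metric.loss_fn is None or metric.loss_grad is None:
        raise ConfigurationError(
            f"metric {name!r} has no gradient and cannot be used as a training loss"
        )
    return metric.loss_fn, metric.loss_grad


def list_metrics() -> Tuple[str, ...]:
    return tuple(sorted(_METRIC_REGISTRY))


def _register_builtins() -> None:
    register_metric(
        "dice_soft", soft_dice,
        loss_fn=lambda t, p: 1.0 - soft_dice(t, p),
        loss_grad=soft_dice_loss_grad,
    )
    register_metric("dice_classwise", lambda t, p: classwise_dice(t, p)[1])
    register_metric("jaccard", jaccard_index)
    register_metric("tversky", tversky_loss, loss_fn=tversky_training_loss,
                    loss_grad=tversky_training_loss_grad)
    register_metric("crossentropy_dice", crossentropy_dice,
                    loss_fn=crossentropy_dice, loss_grad=crossentropy_dice_grad)


_register_builtins()


def reset_metrics() -> None:
    """Restore the registry to the built-in metrics (test isolation helper)."""
    _METRIC_REGISTRY.clear()
    _register_builtins()
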