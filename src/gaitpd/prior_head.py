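"""Prior-information adjustment of the frozen classifier.

Seven physiological priors (sex, age, height, weight, BMI, shoe size,
single-step duration) are z-score-standardized and passed through a
bias-free 7 x 2 linear map; the adjustment is added to the frozen model's
softmax output and re-normalized by a final softmax. Only the 7 x 2 matrix
is trained; because the inputs are standardized and the layer has no bias,
its weights are directly interpretable as signed per-prior influences on
the PD decision (positive = pushes toward PD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .objective import LossWeights, weighted_cross_entropy
from .skeleton_io import PRIOR_FIELDS, PriorVector
from .train_eval import AdamW

__all__ = ["PriorStats", "PriorHead", "standardize_priors",
           "adjust_with_priors", "fit_prior_head"]


@dataclass
class PriorStats:
    """Field-wise standardization statistics, fitted on training subjects."""

    mu: np.ndarray
    sd: np.ndarray
    constant_fields: list[str] = field(default_factory=list)

    @staticmethod
    def fit(priors: list[PriorVector]) -> "PriorStats":
        arr = np.stack([p.as_array() for p in priors])
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0)
        # rounding can leave a ~1e-16 std on a constant field
        zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
        constant = [PRIOR_FIELDS[i] for i in np.nonzero(zero)[0]]
        sd = np.where(zero, 1.0, sd)  # constant fields pass through centred
        return PriorStats(mu=mu, sd=sd, constant_fields=constant)


@dataclass
class PriorHead:
    """Bias-free 7 x 2 adjustment map plus its input statistics."""

    weight: np.ndarray  # (7, 2)
    stats: PriorStats

    def __post_init__(self):
        if self.weight.shape != (len(PRIOR_FIELDS), 2):
            raise ValueError(f"prior head weight must be ({len(PRIOR_FIELDS)}, 2)")

    def weight_table(self) -> dict[str, float]:
        """Signed per-prior influence on the PD class (column 1 - column 0)."""
        delta = self.weight[:, 1] - self.weight[:, 0]
        return dict(zip(PRIOR_FIELDS, map(float, delta)))


def standardize_priors(
    priors: list[PriorVector], stats: PriorStats
) -> np.ndarray:
    """Per-field z-scores, (n, 7) in the documented prior order."""
    arr = np.stack([p.as_array() for p in priors])
    if not np.all(np.isfinite(arr)):
        raise ValueError("priors mode requires complete, finite prior vectors")
    return (arr - stats.mu) / stats.sd


def adjust_with_priors(
    base_probs: np.ndarray, std_priors: np.ndarray, head: PriorHead
) -> np.ndarray:
    """softmax(base softmax output + priors . W); base model untouched.

    Adding the adjustment to the *probabilities* (not the logits) and
    re-normalizing is deliberate; a ``logit`` mode is available through
    :func:`fit_prior_head`'s ``mode`` argument.
    """
    base_probs = np.atleast_2d(np.asarray(base_probs, dtype=float))
    std_priors = np.atleast_2d(np.asarray(std_priors, dtype=float))
    logits = base_probs + std_priors @ head.weight
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def fit_prior_head(
    base_probs: np.ndarray,
    priors: list[PriorVector],
    labels: np.ndarray,
    weights: LossWeights | None = None,
    epochs: int = 500,
    lr: float = 1e-2,
    mode: str = "softmax",
    seed: int = 0,
) -> PriorHead:
    """Fine-tune only the 7 x 2 adjustment matrix on frozen model outputs.

    ``base_probs`` are the frozen model's softmax outputs for the training
    samples (the base network's parameters are not touched — it never
    appears here). The loss is the same class-weighted cross-entropy with
    L1/L2 on the matrix; the stream-discrepancy term does not apply (no
    stream features are involved).
    """
    weights = weights or LossWeights()
    if len(priors) != len(base_probs):
        raise ValueError("need one prior vector per sample")
    stats = PriorStats.fit(priors)
    Z = standardize_priors(priors, stats)
    base = np.asarray(base_probs, dtype=float)
    labels = np.asarray(labels)
    W = Tensor(np.zeros((len(PRIOR_FIELDS), 2)), requires_grad=True)
    opt = AdamW([W])
    baseT = Tensor(base)
    if mode == "logit":
        eps = 1e-7
        baseT = Tensor(np.log(np.clip(base, eps, 1 - eps)))
    elif mode != "softmax":
        raise ValueError("mode must be 'softmax' or 'logit'")
    ZT = Tensor(Z)
    for _ in range(epochs):
        logits = baseT + ZT @ W
        probs = logits.softmax(axis=-1)
        loss = weighted_cross_entropy(probs, labels, weights.w1, weights.w2)
        loss = loss + weights.lambda2 * W.abs().sum() + weights.lambda3 * (W * W).sum()
        opt.zero_grad()
        loss.backward()
        opt.step(lr)
    return PriorHead(weight=W.data.copy(), stats=stats)
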