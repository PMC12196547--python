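"""Composite training objective.

Total loss  L = L_w + lambda1 * L_d + lambda2 * ||W||_1 + lambda3 * ||W||_2^2

* ``L_w``  — class-weighted cross-entropy (mean over the batch); w1
  multiplies the PD-label (y = 1) term and w2 the HC-label term, the
  tuned setting being w1 = 0.9, w2 = 1.1.
* ``L_d``  — mean over layers of the (clamped) squared maximum mean
  discrepancy between the frontal and lateral streams' features, with a
  Gaussian kernel whose bandwidth follows the median heuristic
  ``gamma = 1 / median(pairwise distance)^2`` on the pooled set.
* ``||W||`` terms — L1/L2 over trainable weight matrices only (biases and
  normalization gains excluded).

The squared-MMD estimator is the unbiased one (within-set sums over i != j
plus the full cross term) and may be slightly negative on finite samples;
the per-layer values are clamped at zero before averaging so the
regularizer cannot reward anti-similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .autodiff import Tensor, as_tensor

__all__ = [
    "LossWeights", "LossBreakdown",
    "kernel_bandwidth", "mmd_squared", "mmd_layer_loss",
    "weighted_cross_entropy", "total_loss",
]

_EPS = 1e-7

#: number of per-view points the per-batch MMD estimate is computed on;
#: larger batches are subsampled (the estimator stays unbiased)
MMD_MAX_POINTS = 64


@dataclass(frozen=True)
class LossWeights:
    """Loss hyperparameters (tuned defaults)."""

    w1: float = 0.9     # weight on the y=1 (PD-label) log-likelihood term
    w2: float = 1.1     # weight on the y=0 (HC-label) term
    lambda1: float = 0.01    # MMD weight
    lambda2: float = 0.0001  # L1 weight
    lambda3: float = 0.001   # L2 weight

    def __post_init__(self):
        if min(self.w1, self.w2, self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    """Decomposed loss terms; ``total`` keeps the autodiff graph."""

    L_w: float
    L_d: float
    l1: float
    l2: float
    total_value: float
    per_layer_D: list[float] = field(default_factory=list)
    total: Tensor | None = None


def kernel_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    """Median-heuristic Gaussian bandwidth on the pooled sample.

    gamma = 1 / median{ ||Z_i - Z_j|| : i < j }^2 with Z = [X; Y].
    Falls back to 1.0 (with a warning) when all points coincide.
    """
    Z = np.vstack([np.asarray(X, dtype=float), np.asarray(Y, dtype=float)])
    if Z.shape[0] < 2:
        raise ValueError("need at least two pooled points for the median heuristic")
    med = np.median(pdist(Z))
    if med == 0:
        warnings.warn("all pooled points identical; falling back to gamma = 1")
        return 1.0
    return float(1.0 / med**2)


def _sq_dists(X: Tensor, Y: Tensor) -> Tensor:
    x2 = (X * X).sum(axis=1, keepdims=True)
    y2 = (Y * Y).sum(axis=1, keepdims=True)
    d2 = x2 + y2.swapaxes(0, 1) - 2.0 * (X @ Y.swapaxes(0, 1))
    return d2.relu()  # guard tiny negative rounding


def _mmd2(X: Tensor, Y: Tensor, gamma: float) -> Tensor:
    n, m = X.shape[0], Y.shape[0]
    Kxx = (_sq_dists(X, X) * (-gamma)).exp()
    Kyy = (_sq_dists(Y, Y) * (-gamma)).exp()
    Kxy = (_sq_dists(X, Y) * (-gamma)).exp()
    within_x = (Kxx.sum() - float(n)) / float(n * (n - 1))
    within_y = (Kyy.sum() - float(m)) / float(m * (m - 1))
    cross = Kxy.sum() * (2.0 / (n * m))
    return within_x + within_y - cross


def mmd_squared(
    X: np.ndarray | Tensor, Y: np.ndarray | Tensor, gamma: float | None = None
) -> float | Tensor:
    """Unbiased squared MMD between samples X (n, d) and Y (m, d).

    With a Gaussian kernel K(x, y) = exp(-gamma ||x - y||^2); ``gamma``
    defaults to the median heuristic. Returns a plain float for array
    inputs and a graph-carrying :class:`Tensor` for tensor inputs.
    """
    tensor_mode = isinstance(X, Tensor) or isinstance(Y, Tensor)
    Xt, Yt = as_tensor(X), as_tensor(Y)
    if Xt.shape[0] < 2 or Yt.shape[0] < 2:
        raise ValueError("unbiased MMD needs at least 2 points per set")
    if gamma is None:
        gamma = kernel_bandwidth(Xt.data, Yt.data)
    out = _mmd2(Xt, Yt, gamma)
    return out if tensor_mode else float(out.data)


def mmd_layer_loss(
    per_layer_frontal: list,
    per_layer_lateral: list,
    max_points: int | None = MMD_MAX_POINTS,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, list[float]]:
    """Mean per-layer stream discrepancy L_d = (1/l) sum_i max(D_i^2, 0).

    Per-sample features are flattened to vectors (time x dim); each layer
    gets its own median-heuristic bandwidth, treated as a constant with
    respect to gradients. Batches larger than ``max_points`` are
    subsampled per layer to bound the O(n^2) kernel cost.
    """
    if len(per_layer_frontal) != len(per_layer_lateral):
        raise ValueError("stream feature lists must have equal layer counts")
    if not per_layer_frontal:
        raise ValueError("no layer features given")
    total: Tensor | None = None
    per_layer: list[float] = []
    for F, L in zip(per_layer_frontal, per_layer_lateral):
        F, L = as_tensor(F), as_tensor(L)
        n = F.shape[0]
        if n < 2 or L.shape[0] < 2:
            raise ValueError("MMD needs a batch of at least 2 samples per view")
        Fv = F.reshape(n, -1)
        Lv = L.reshape(L.shape[0], -1)
        if max_points is not None and n > max_points:
            idx = (rng or np.random.default_rng()).choice(n, max_points, replace=False)
            idx.sort()
            Fv, Lv = Fv[idx], Lv[idx]
        gamma = kernel_bandwidth(Fv.data, Lv.data)
        d2 = _mmd2(Fv, Lv, gamma).relu()  # clamp: D_i = max(D_i^2, 0)
        per_layer.append(float(d2.data))
        total = d2 if total is None else total + d2
    return total / float(len(per_layer)), per_layer


def weighted_cross_entropy(
    probs: np.ndarray | Tensor,
    labels: np.ndarray,
    w1: float = 0.9,
    w2: float = 1.1,
) -> Tensor:
    """Class-weighted binary cross-entropy, mean-reduced over the batch.

    ``probs`` is (b, 2) with column 1 the PD probability p_i; the y_i = 1
    (PD) term is weighted by w1 and the y_i = 0 term by w2:
    L_w = -mean_i [ w1 y_i log p_i + w2 (1 - y_i) log(1 - p_i) ].
    """
    probs = as_tensor(probs)
    y = np.asarray(labels, dtype=probs.dtype)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("probs must be (batch, 2)")
    p = probs[:, 1].clip(_EPS, 1.0 - _EPS)
    ll = p.log() * (w1 * y) + (1.0 - p).log() * (w2 * (1.0 - y))
    return -ll.mean()


def _weight_norms(weight_matrices: list[Tensor]) -> tuple[Tensor, Tensor]:
    l1: Tensor | None = None
    l2: Tensor | None = None
    for W in weight_matrices:
        a = W.abs().sum()
        s = (W * W).sum()
        l1 = a if l1 is None else l1 + a
        l2 = s if l2 is None else l2 + s
    if l1 is None:
        l1, l2 = Tensor(0.0), Tensor(0.0)
    return l1, l2


def total_loss(
    probs: Tensor,
    labels: np.ndarray,
    per_layer_frontal: list[Tensor],
    per_layer_lateral: list[Tensor],
    weights: LossWeights,
    weight_matrices: list[Tensor] | None = None,
    rng: np.random.Generator | None = None,
) -> LossBreakdown:
    """Assemble L = L_w + lambda1 L_d + lambda2 ||W||_1 + lambda3 ||W||_2^2."""
    L_w = weighted_cross_entropy(probs, labels, weights.w1, weights.w2)
    if weights.lambda1 > 0 and per_layer_frontal:
        L_d, per_layer = mmd_layer_loss(per_layer_frontal, per_layer_lateral, rng=rng)
    else:
        L_d, per_layer = Tensor(0.0), []
    l1, l2 = _weight_norms(weight_matrices or [])
    total = L_w + weights.lambda1 * L_d + weights.lambda2 * l1 + weights.lambda3 * l2
    for name, term in (("L_w", L_w), ("L_d", L_d), ("l1", l1), ("l2", l2)):
        if not np.isfinite(term.data):
            raise FloatingPointError(f"non-finite loss component: {name}")
    return LossBreakdown(
        L_w=float(L_w.data), L_d=float(L_d.data), l1=float(l1.data),
        l2=float(l2.data), total_value=float(total.data),
        per_layer_D=per_layer, total=total,
    )
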