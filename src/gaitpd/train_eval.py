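"""Training schedule, subject-grouped cross-validation and metrics.

Evaluation is leakage-free by construction: folds partition *subjects*
(no individual contributes steps to both training and validation of a
fold), and z-score statistics are fitted on the training folds only. The
positive class is PD throughout; the evaluation unit is the single step
(a subject-level majority-vote summary is reported additionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .autodiff import Tensor
from .network import CMSANet, ModelConfig
from .normalization import StepSample, ZScoreStats, apply_zscore, fit_zscore
from .objective import LossWeights, total_loss

__all__ = [
    "TrainConfig", "ConfusionCounts", "FoldResult", "MetricsReport", "AdamW",
    "learning_rate", "grouped_kfold", "compute_metrics", "f1_from_pr",
    "roc_auc", "aggregate_folds", "predict_samples", "run_training",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule (defaults follow the full training protocol).

    The learning rate ramps linearly from ``lr_init`` to ``lr_peak`` over
    the warm-up epochs, holds, then decays linearly to ``lr_final``.
    """

    batch_size: int = 3072
    epochs: int = 1000
    warmup_epochs: int = 200
    constant_epochs: int = 400
    decay_epochs: int = 400
    lr_init: float = 1e-8
    lr_peak: float = 1e-4
    lr_final: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.99
    grad_clip: float = 1.0
    decay_shape: str = "linear"  # or "cosine"
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs + self.constant_epochs + self.decay_epochs != self.epochs:
            raise ValueError("phase lengths must sum to total epochs")

    @staticmethod
    def reduced(seed: int = 0) -> "TrainConfig":
        """Desk-scale configuration: same 20/40/40 phase proportions,
        magnitudes rescaled so ~10^2 optimizer steps suffice."""
        return TrainConfig(
            batch_size=256, epochs=60,
            warmup_epochs=12, constant_epochs=24, decay_epochs=24,
            lr_init=1e-6, lr_peak=2e-3, lr_final=2e-5, seed=seed,
        )


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise warm-up / constant / decay schedule, indexed by epoch."""
    if epoch < 0 or epoch > cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    w, c = cfg.warmup_epochs, cfg.constant_epochs
    if epoch < w:
        return cfg.lr_init + (cfg.lr_peak - cfg.lr_init) * (epoch / w)
    if epoch < w + c:
        return cfg.lr_peak
    frac = (epoch - w - c) / cfg.decay_epochs
    if cfg.decay_shape == "cosine":
        return cfg.lr_final + (cfg.lr_peak - cfg.lr_final) * 0.5 * (1 + np.cos(np.pi * frac))
    return cfg.lr_peak + (cfg.lr_final - cfg.lr_peak) * frac


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @staticmethod
    def from_predictions(pred: np.ndarray, labels: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred).astype(int)
        labels = np.asarray(labels).astype(int)
        return ConfusionCounts(
            TP=int(np.sum((pred == 1) & (labels == 1))),
            TN=int(np.sum((pred == 0) & (labels == 0))),
            FP=int(np.sum((pred == 1) & (labels == 0))),
            FN=int(np.sum((pred == 0) & (labels == 1))),
        )


@dataclass
class FoldResult:
    """Validation metrics of one fold, in percent (AUC in [0, 1])."""

    acc: float
    prec: float
    rec: float
    f1: float
    auc: float = float("nan")
    undefined: list[str] = field(default_factory=list)
    best_epoch: int = -1
    train_acc: float = float("nan")


@dataclass
class MetricsReport:
    folds: list[FoldResult]
    mean: FoldResult


def compute_metrics(counts: ConfusionCounts) -> FoldResult:
    """Accuracy / precision / recall / F1 (percent) from confusion counts."""
    undefined = []
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    acc = 100.0 * (counts.TP + counts.TN) / counts.total
    if counts.TP + counts.FP == 0:
        prec = 0.0
        undefined.append("precision")
    else:
        prec = 100.0 * counts.TP / (counts.TP + counts.FP)
    if counts.TP + counts.FN == 0:
        rec = 0.0
        undefined.append("recall")
    else:
        rec = 100.0 * counts.TP / (counts.TP + counts.FN)
    if prec + rec == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = f1_from_pr(prec, rec)
    return FoldResult(acc=acc, prec=prec, rec=rec, f1=f1, undefined=undefined)


def f1_from_pr(prec: float, rec: float) -> float:
    """Harmonic mean of precision and recall (same units as the inputs)."""
    return 2.0 * prec * rec / (prec + rec)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random PD score > random HC score), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def aggregate_folds(folds: list[FoldResult]) -> MetricsReport:
    """Arithmetic mean of each per-fold metric."""
    if not folds:
        raise ValueError("no folds to aggregate")
    mean = FoldResult(
        acc=float(np.mean([f.acc for f in folds])),
        prec=float(np.mean([f.prec for f in folds])),
        rec=float(np.mean([f.rec for f in folds])),
        f1=float(np.mean([f.f1 for f in folds])),
        auc=float(np.mean([f.auc for f in folds])),
        train_acc=float(np.mean([f.train_acc for f in folds])),
    )
    return MetricsReport(folds=list(folds), mean=mean)


# ------------------------------------------------------------- grouping

def grouped_kfold(samples: list[StepSample], k: int = 5, seed: int = 0) -> np.ndarray:
    """Subject-level k-fold partition, balanced in subject count and class.

    Within each class, subjects are assigned greedily (descending sample
    count, seed-shuffled ties) to the fold with the fewest subjects of
    that class, ties broken by total sample count then fold index.
    Deterministic given the seed. Returns the fold index of every sample.
    """
    subjects: dict[str, dict] = {}
    for i, s in enumerate(samples):
        rec = subjects.setdefault(s.subject_id, {"label": s.label, "idx": []})
        if rec["label"] != s.label:
            raise ValueError(f"subject {s.subject_id} has inconsistent labels")
        rec["idx"].append(i)
    if len(subjects) < k:
        raise ValueError(f"need at least {k} distinct subjects, have {len(subjects)}")
    rng = np.random.default_rng(seed)
    fold_of_subject: dict[str, int] = {}
    class_counts = np.zeros((k, 2), dtype=int)   # subjects per fold per class
    sample_counts = np.zeros(k, dtype=int)
    for label in (1, 0):  # minority class placed first
        group = [sid for sid, rec in subjects.items() if rec["label"] == label]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        group.sort(key=lambda sid: -len(subjects[sid]["idx"]))  # stable: keeps shuffle for ties
        for sid in group:
            key = [(class_counts[f, label], sample_counts[f], f) for f in range(k)]
            f = min(range(k), key=lambda j: key[j])
            fold_of_subject[sid] = f
            class_counts[f, label] += 1
            sample_counts[f] += len(subjects[sid]["idx"])
    out = np.empty(len(samples), dtype=int)
    for sid, rec in subjects.items():
        out[rec["idx"]] = fold_of_subject[sid]
    return out


# ------------------------------------------------------------ optimizer

class AdamW(object):
    """AdamW with decoupled weight decay (decay defaults to 0: the explicit
    L1/L2 terms in the objective play that role)."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps, self.wd = beta1, beta2, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float, grad_clip: float = 0.0):
        if grad_clip > 0:
            norm2 = sum(float(np.sum(p.grad**2)) for p in self.params if p.grad is not None)
            norm = np.sqrt(norm2)
            scale = grad_clip / norm if norm > grad_clip else 1.0
        else:
            scale = 1.0
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.wd:
                update = update + self.wd * p.data
            p.data = (p.data - lr * update).astype(p.data.dtype)


# -------------------------------------------------------------- training

def predict_samples(
    model: CMSANet, samples: list[StepSample], batch_size: int = 512
) -> np.ndarray:
    """PD-class probabilities for a list of standardized samples."""
    probs = []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo: lo + batch_size]
        xf = np.stack([s.frontal for s in chunk]).astype(np.float32)
        xl = np.stack([s.lateral for s in chunk]).astype(np.float32)
        p, _, _ = model.forward(xf, xl, rng=None)
        probs.append(p.data[:, 1])
    return np.concatenate(probs)


def _evaluate(model: CMSANet, samples: list[StepSample]) -> tuple[FoldResult, np.ndarray]:
    labels = np.array([s.label for s in samples])
    scores = predict_samples(model, samples)
    counts = ConfusionCounts.from_predictions((scores > 0.5).astype(int), labels)
    res = compute_metrics(counts)
    if len(np.unique(labels)) == 2:
        res.auc = roc_auc(scores, labels)
    return res, scores


@dataclass
class FoldArtifacts:
    result: FoldResult
    model: CMSANet
    stats: ZScoreStats
    history: list[dict]
    val_scores: np.ndarray
    val_labels: np.ndarray
    val_subjects: list[str]


@dataclass
class TrainingResult:
    report: MetricsReport
    folds: list[FoldArtifacts]
    fold_assignment: np.ndarray

    def pooled_validation_auc(self) -> float:
        scores = np.concatenate([f.val_scores for f in self.folds])
        labels = np.concatenate([f.val_labels for f in self.folds])
        return roc_auc(scores, labels)

    def subject_majority_report(self) -> dict[str, float]:
        """Subject-level accuracy by majority vote over each subject's steps."""
        votes: dict[str, list] = {}
        truth: dict[str, int] = {}
        for f in self.folds:
            for sid, score, lab in zip(f.val_subjects, f.val_scores, f.val_labels):
                votes.setdefault(sid, []).append(score > 0.5)
                truth[sid] = int(lab)
        correct = sum(
            int((np.mean(v) > 0.5) == truth[sid]) for sid, v in votes.items()
        )
        return {"subject_accuracy": 100.0 * correct / len(votes), "n_subjects": len(votes)}


def _train_one_fold(
    train: list[StepSample],
    val: list[StepSample],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    weights: LossWeights,
    seed: int,
) -> FoldArtifacts:
    stats = fit_zscore(train)
    train_z = apply_zscore(train, stats)
    val_z = apply_zscore(val, stats)
    model = CMSANet(model_cfg, seed=seed)
    opt = AdamW(model.parameters(), beta1=cfg.beta1, beta2=cfg.beta2)
    wmats = model.weight_matrices()
    rng = np.random.default_rng(seed + 1)

    xf = np.stack([s.frontal for s in train_z]).astype(np.float32)
    xl = np.stack([s.lateral for s in train_z]).astype(np.float32)
    y = np.array([s.label for s in train_z])
    n = len(train_z)

    best_f1, best_epoch, best_state = -1.0, -1, None
    best_val: FoldResult | None = None
    best_scores: np.ndarray | None = None
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = learning_rate(epoch, cfg)
        perm = rng.permutation(n)
        ep_loss = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo: lo + cfg.batch_size]
            if idx.size < 2:
                continue  # MMD undefined on singleton batches
            probs, ff, fl = model.forward(
                Tensor(xf[idx]), Tensor(xl[idx]), rng=rng
            )
            bd = total_loss(probs, y[idx], ff, fl, weights, wmats, rng=rng)
            opt.zero_grad()
            bd.total.backward()
            opt.step(lr, grad_clip=cfg.grad_clip)
            ep_loss.append(bd)
        val_res, val_scores = _evaluate(model, val_z)
        history.append({
            "epoch": epoch, "lr": lr,
            "loss": float(np.mean([b.total_value for b in ep_loss])),
            "L_w": float(np.mean([b.L_w for b in ep_loss])),
            "L_d": float(np.mean([b.L_d for b in ep_loss])),
            "l1": float(np.mean([b.l1 for b in ep_loss])),
            "l2": float(np.mean([b.l2 for b in ep_loss])),
            "val_f1": val_res.f1, "val_acc": val_res.acc, "val_auc": val_res.auc,
        })
        if val_res.f1 > best_f1:
            best_f1, best_epoch = val_res.f1, epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            best_val, best_scores = val_res, val_scores
    model.load_state_dict(best_state)
    train_res, _ = _evaluate(model, train_z)
    best_val.best_epoch = best_epoch
    best_val.train_acc = train_res.acc
    return FoldArtifacts(
        result=best_val, model=model, stats=stats, history=history,
        val_scores=best_scores, val_labels=np.array([s.label for s in val_z]),
        val_subjects=[s.subject_id for s in val_z],
    )


def run_training(
    samples: list[StepSample],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    weights: LossWeights | None = None,
    k: int = 5,
) -> TrainingResult:
    """Subject-grouped k-fold training with best-F1 checkpointing per fold.

    ``samples`` are *unstandardized* step samples; z-score statistics are
    fitted inside each fold on its training portion only.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    weights = weights or LossWeights()
    assignment = grouped_kfold(samples, k=k, seed=train_cfg.seed)
    folds: list[FoldArtifacts] = []
    for f in range(k):
        train = [s for s, a in zip(samples, assignment) if a != f]
        val = [s for s, a in zip(samples, assignment) if a == f]
        folds.append(
            _train_one_fold(train, val, model_cfg, train_cfg, weights,
                            seed=(train_cfg.seed * 1000 + f) % (2**31 - 1))
        )
    report = aggregate_folds([fa.result for fa in folds])
    return TrainingResult(report=report, folds=folds, fold_assignment=assignment)
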