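"""Scaling, resampling and standardization of segmented steps.

Each single step is brought to a camera-distance-invariant scale
(x centred, y in [0, 1], aspect ratio preserved: both coordinates divided
by the step's y-range), linearly resampled to exactly 50 frames, and the
assembled dataset is z-scored per feature column with statistics taken from
the training portion only.

The model input per view is a (50, 39) matrix: 13 joints x (x', y', conf),
interleaved per joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton_io import DualViewRecording, JointLayout, select_joints
from .step_segmentation import StepBoundary

__all__ = [
    "StepSample", "ZScoreStats", "DegenerateStepError",
    "scale_step", "resample_step", "step_to_features",
    "build_step_samples", "fit_zscore", "apply_zscore", "zscore_dataset",
]

TARGET_FRAMES = 50
N_FEATURES = 39  # 13 joints x (x, y, conf)


class DegenerateStepError(ValueError):
    """Raised for steps that cannot be normalized (flat y-range, < 2 frames)."""


@dataclass
class StepSample:
    """One segmented, normalized single step.

    ``frontal`` / ``lateral`` are (50, 39) feature matrices; ``label`` is
    0 = healthy control, 1 = Parkinson's disease.
    """

    subject_id: str
    label: int
    frontal: np.ndarray
    lateral: np.ndarray
    raw_length: int

    def __post_init__(self):
        for name in ("frontal", "lateral"):
            m = getattr(self, name)
            if m.shape != (TARGET_FRAMES, N_FEATURES):
                raise ValueError(
                    f"{name} view must be ({TARGET_FRAMES}, {N_FEATURES}), got {m.shape}"
                )


@dataclass
class ZScoreStats:
    """Per-column mean/sd for each view, fitted on training data only."""

    mu_frontal: np.ndarray
    sd_frontal: np.ndarray
    mu_lateral: np.ndarray
    sd_lateral: np.ndarray
    constant_columns: list[str] = field(default_factory=list)


def scale_step(step: np.ndarray) -> np.ndarray:
    """Scale one view's keypoint slice of a step to a common body scale.

    ``step`` is (frames, 13, 3). Over all frames and joints of the step,
    x' = (x - mean(x)) / (max(y) - min(y)) and
    y' = (y - min(y)) / (max(y) - min(y)); the shared divisor preserves the
    aspect ratio, and confidences pass through untouched.
    """
    step = np.asarray(step, dtype=float)
    if step.ndim != 3 or step.shape[2] != 3:
        raise ValueError("step slice must be (frames, joints, 3)")
    x, y = step[:, :, 0], step[:, :, 1]
    y_range = y.max() - y.min()
    if y_range <= 0:
        raise DegenerateStepError("step has zero vertical extent (max(y) == min(y))")
    out = step.copy()
    out[:, :, 0] = (x - x.mean()) / y_range
    out[:, :, 1] = (y - y.min()) / y_range
    return out


def resample_step(step: np.ndarray, target_len: int = TARGET_FRAMES) -> np.ndarray:
    """Resample every channel to ``target_len`` frames.

    Piecewise-linear interpolation on a uniform grid including both
    endpoints, used identically for up- and down-sampling.
    """
    step = np.asarray(step, dtype=float)
    n = step.shape[0]
    if n < 2:
        raise DegenerateStepError("cannot resample a single-frame step")
    if n == target_len:
        return step.copy()
    old = np.arange(n, dtype=float)
    new = np.linspace(0.0, n - 1, target_len)
    flat = step.reshape(n, -1)
    res = np.empty((target_len, flat.shape[1]))
    for c in range(flat.shape[1]):
        res[:, c] = np.interp(new, old, flat[:, c])
    return res.reshape((target_len,) + step.shape[1:])


def trim_step(step: np.ndarray, target_len: int = TARGET_FRAMES) -> np.ndarray:
    """Alternative length adjustment: trim (or linearly upsample short steps)."""
    step = np.asarray(step, dtype=float)
    if step.shape[0] >= target_len:
        return step[:target_len].copy()
    return resample_step(step, target_len)


def step_to_features(step: np.ndarray) -> np.ndarray:
    """Flatten a (50, 13, 3) normalized slice to the (50, 39) model input."""
    return step.reshape(step.shape[0], -1)


def build_step_samples(
    rec: DualViewRecording,
    boundaries: list[StepBoundary],
    label: int,
    mode: str = "interp",
) -> list[StepSample]:
    """Cut, scale and resample all steps of one recording (both views)."""
    frontal = rec.frontal if rec.frontal.joint_layout is JointLayout.REDUCED13 \
        else select_joints(rec.frontal)
    lateral = rec.lateral if rec.lateral.joint_layout is JointLayout.REDUCED13 \
        else select_joints(rec.lateral)
    adjust = resample_step if mode == "interp" else trim_step
    samples = []
    for b in boundaries:
        sl = slice(b.start_frame, b.end_frame + 1)
        try:
            f = step_to_features(adjust(scale_step(frontal.data[sl])))
            l = step_to_features(adjust(scale_step(lateral.data[sl])))
        except DegenerateStepError:
            continue
        samples.append(
            StepSample(rec.subject_id, int(label), f, l, raw_length=b.n_frames)
        )
    return samples


def fit_zscore(samples: list[StepSample]) -> ZScoreStats:
    """Per-feature-column mean/sd over all frames of all (training) samples."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit z-score statistics")
    stats = {}
    constant = []
    for view in ("frontal", "lateral"):
        data = np.concatenate([getattr(s, view) for s in samples], axis=0)
        mu = data.mean(axis=0)
        sd = data.std(axis=0)
        zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
        if zero.any():
            constant += [f"{view}:{i}" for i in np.nonzero(zero)[0]]
            sd = np.where(zero, 1.0, sd)  # pass constant columns through centred
        stats[view] = (mu, sd)
    return ZScoreStats(
        mu_frontal=stats["frontal"][0], sd_frontal=stats["frontal"][1],
        mu_lateral=stats["lateral"][0], sd_lateral=stats["lateral"][1],
        constant_columns=constant,
    )


def apply_zscore(samples: list[StepSample], stats: ZScoreStats) -> list[StepSample]:
    """Standardize samples with stored statistics (reusable on held-out data)."""
    out = []
    for s in samples:
        out.append(
            StepSample(
                s.subject_id, s.label,
                (s.frontal - stats.mu_frontal) / stats.sd_frontal,
                (s.lateral - stats.mu_lateral) / stats.sd_lateral,
                s.raw_length,
            )
        )
    return out


def zscore_dataset(
    samples: list[StepSample],
) -> tuple[list[StepSample], ZScoreStats]:
    """Fit z-score statistics on `samples` and return standardized copies."""
    stats = fit_zscore(samples)
    return apply_zscore(samples, stats), stats
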