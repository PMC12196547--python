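"""Single-step segmentation of continuous walking recordings.

A *single step* is the span from one right-foot landing to the next
left-foot landing. Landings are frames where the foot touches the ground,
i.e. local minima of the ankle's elevation. The lateral view's ankle
y-coordinate tracks foot height directly, so segmentation is computed there
and the resulting frame boundaries are applied to both synchronized views.

Pipeline: Savitzky-Golay smoothing of the ankle elevation (preserves the
positions of extrema), then local-minimum selection on the negated curve
with a prominence threshold tied to the subject's apparent body height
(mean head-to-foot pixel distance / 20), then right->left pairing, and
finally removal of steps that touch stationary spans or fall outside
plausible duration bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .skeleton_io import (
    R13_LEFT_ANKLE,
    R13_NOSE,
    R13_RIGHT_ANKLE,
    DualViewRecording,
    JointLayout,
    KeypointSequence,
    View,
    select_joints,
)

__all__ = [
    "FilterParams", "PeakParams", "StepBoundary",
    "smooth_signal", "foot_elevation", "detect_landings", "mean_height",
    "stationary_mask", "extract_steps",
]

#: plausible single-step duration bounds in frames (average step ~= 50)
MIN_STEP_FRAMES = 20
MAX_STEP_FRAMES = 120


@dataclass(frozen=True)
class FilterParams:
    """Savitzky-Golay smoothing parameters (defaults: window 45, order 6)."""

    window_size: int = 45
    poly_order: int = 6

    def __post_init__(self):
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")
        if self.window_size <= self.poly_order:
            raise ValueError("window_size must exceed poly_order")


@dataclass(frozen=True)
class PeakParams:
    """Sliding-window minimum selection parameters.

    ``window_size`` is the local-extremum neighbourhood, ``min_separation``
    a post-filter on inter-landing gaps, and ``prominence_threshold`` the
    minimum peak prominence (defaults to mean body height / 20, set by the
    caller via :func:`mean_height`).
    """

    window_size: int = 30
    min_separation: int = 30
    prominence_threshold: float = 1.0

    def __post_init__(self):
        if self.window_size <= 0 or self.min_separation <= 0:
            raise ValueError("window_size and min_separation must be positive")
        if self.prominence_threshold < 0:
            raise ValueError("prominence_threshold must be non-negative")


@dataclass(frozen=True)
class StepBoundary:
    """Frame span of one single step: right-foot landing -> left-foot landing."""

    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.start_frame >= self.end_frame:
            raise ValueError("start_frame must precede end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def smooth_signal(signal: np.ndarray, params: FilterParams = FilterParams()) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing; exact on polynomials up to
    ``poly_order``. Edge frames use a polynomial fit on the truncated edge
    window rather than padded data."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("smooth_signal expects a 1-D series")
    if signal.size < params.window_size:
        raise ValueError(
            f"series of length {signal.size} shorter than SG window "
            f"{params.window_size}; skip this recording"
        )
    return savgol_filter(signal, params.window_size, params.poly_order, mode="interp")


def foot_elevation(
    seq: KeypointSequence, side: str, y_axis: str = "down"
) -> np.ndarray:
    """Ankle elevation series for one foot from the lateral view.

    Under image convention (``y_axis='down'``) elevation is the negated
    pixel y, so ground contacts are local minima of the returned series.
    """
    if seq.view is not View.LATERAL:
        raise ValueError("foot elevation requires the lateral view")
    if seq.joint_layout is not JointLayout.REDUCED13:
        seq = select_joints(seq)
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    idx = R13_LEFT_ANKLE if side == "left" else R13_RIGHT_ANKLE
    y = seq.data[:, idx, 1]
    if y_axis == "down":
        return -y
    if y_axis == "up":
        return y.copy()
    raise ValueError("y_axis must be 'down' or 'up'")


def mean_height(seq: KeypointSequence) -> float:
    """Mean per-frame body height in pixels: |y_head - mean(y_ankles)|.

    Sets the prominence threshold scale (threshold = mean_height / 20).
    """
    if seq.joint_layout is not JointLayout.REDUCED13:
        seq = select_joints(seq)
    y = seq.data[:, :, 1]
    head = y[:, R13_NOSE]
    feet = 0.5 * (y[:, R13_LEFT_ANKLE] + y[:, R13_RIGHT_ANKLE])
    return float(np.mean(np.abs(head - feet)))


def _local_minima_candidates(neg: np.ndarray, window: int) -> np.ndarray:
    """Indices that are maxima of `neg` within a +-window neighbourhood.

    Plateau runs contribute their first index (deterministic tie-break).
    """
    n = neg.size
    out = []
    i = 0
    while i < n:
        lo, hi = max(0, i - window), min(n, i + window + 1)
        seg = neg[lo:hi]
        if neg[i] >= seg.max():
            # skip plateau duplicates: only the first index of an equal run
            if i > 0 and neg[i - 1] == neg[i]:
                i += 1
                continue
            out.append(i)
        i += 1
    return np.asarray(out, dtype=int)


def _prominence(neg: np.ndarray, c: int) -> float:
    """Peak prominence of ``neg[c]``, one-sided at the series edges.

    A landing can legitimately sit on the first or last frame, where the
    textbook definition degenerates; the available side's trough is used
    instead of rejecting the peak outright.
    """
    h = neg[c]
    bases = []
    i = c - 1
    side_min = h
    while i >= 0 and neg[i] <= h:
        side_min = min(side_min, neg[i])
        i -= 1
    if i >= 0 or c > 0:
        bases.append(side_min)
    i = c + 1
    side_min = h
    n = neg.size
    while i < n and neg[i] <= h:
        side_min = min(side_min, neg[i])
        i += 1
    if i < n or c < n - 1:
        bases.append(side_min)
    if not bases:
        return 0.0
    return float(h - max(bases))


def detect_landings(
    elevation: np.ndarray, params: PeakParams
) -> np.ndarray:
    """Frames of foot landings: local minima of a smoothed elevation series.

    The negated curve is scanned for windowed local maxima; candidates below
    ``prominence_threshold`` (stable regions) are rejected, then candidates
    closer than ``min_separation`` are resolved greedily by prominence
    (ties: the earlier frame wins).
    """
    elevation = np.asarray(elevation, dtype=float)
    if elevation.size == 0:
        raise ValueError("empty elevation series")
    neg = -elevation
    cand = _local_minima_candidates(neg, params.window_size)
    if cand.size == 0:
        return np.empty(0, dtype=int)
    prom = np.array([_prominence(neg, int(c)) for c in cand])
    keep = (prom > 0) & (prom >= params.prominence_threshold)
    cand, prom = cand[keep], prom[keep]
    if cand.size == 0:
        return np.empty(0, dtype=int)
    # greedy non-maximum suppression: by descending prominence, earlier first
    order = np.lexsort((cand, -prom))
    chosen: list[int] = []
    for idx in order:
        c = cand[idx]
        if all(abs(c - s) >= params.min_separation for s in chosen):
            chosen.append(int(c))
    return np.asarray(sorted(chosen), dtype=int)


def stationary_mask(
    elevation_smooth: np.ndarray, params: PeakParams
) -> np.ndarray:
    """Boolean mask of frames inside stationary spans.

    A frame is stationary when the peak-to-trough amplitude of the smoothed
    elevation over a centred sliding window (width = peak window) stays
    below the prominence threshold — i.e. the foot never lifts appreciably.
    """
    x = np.asarray(elevation_smooth, dtype=float)
    n = x.size
    w = params.window_size
    mask = np.empty(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        seg = x[lo:hi]
        mask[i] = (seg.max() - seg.min()) < params.prominence_threshold
    return mask


def extract_steps(
    rec: DualViewRecording,
    fp: FilterParams = FilterParams(),
    pp: PeakParams | None = None,
    y_axis: str = "down",
) -> list[StepBoundary]:
    """Cut a continuous recording into single steps.

    Right-ankle and left-ankle landing lists are detected on SG-smoothed
    lateral elevations; each right landing ``r`` is paired with the first
    left landing after it and before the next right landing. Steps
    intersecting stationary spans or with implausible durations are dropped.
    The boundaries apply to both views (they are temporally aligned).
    """
    lateral = rec.lateral
    if lateral.joint_layout is not JointLayout.REDUCED13:
        lateral = select_joints(lateral)
    if pp is None:
        pp = PeakParams(prominence_threshold=mean_height(lateral) / 20.0)

    if lateral.n_frames < fp.window_size:
        return []
    elev_r = smooth_signal(foot_elevation(lateral, "right", y_axis), fp)
    elev_l = smooth_signal(foot_elevation(lateral, "left", y_axis), fp)
    right = detect_landings(elev_r, pp)
    left = detect_landings(elev_l, pp)
    if right.size == 0 or left.size == 0:
        return []

    stat = stationary_mask(elev_r, pp) & stationary_mask(elev_l, pp)

    boundaries: list[StepBoundary] = []
    for i, r in enumerate(right):
        nxt = right[i + 1] if i + 1 < right.size else np.inf
        after = left[(left > r) & (left < nxt)]
        if after.size == 0:
            continue
        l = int(after[0])
        n = l - int(r) + 1
        if n < MIN_STEP_FRAMES or n > MAX_STEP_FRAMES:
            continue
        if stat[int(r): l + 1].any():
            continue
        boundaries.append(StepBoundary(int(r), l))
    return boundaries
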