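"""Synthetic dual-view gait generator with known step boundaries.

Emulates the study conditions of a dual-camera walking recording: two
synchronized views at 30 fps of a subject walking with periodic foot
lifts, a stationary prefix/suffix, class-dependent gait structure
(reduced stride amplitude and step length, slower cadence, elevated
high-frequency tremor for the PD class), a ~0.72:0.28 HC:PD cohort
imbalance, and single-step durations averaging ~50 frames.

The kinematics are phenomenological — sinusoidal foot-lift curves with an
initiation/termination envelope, a rigid vertical body stack with bob,
lateral sway and a distance-dependent scale in the frontal view — which is
sufficient to exercise segmentation, normalization, fusion and training;
it is not a biomechanical simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .normalization import StepSample, build_step_samples
from .skeleton_io import (
    DualViewRecording,
    KeypointSequence,
    PriorVector,
    View,
    make_dual_view_sample,
)
from .step_segmentation import FilterParams, PeakParams, StepBoundary, extract_steps

__all__ = ["GaitParams", "GroundTruth", "CohortData",
           "synth_subject", "synth_cohort", "cohort_to_samples"]

FPS = 30.0
_IMG_W, _IMG_H = 1920.0, 1080.0


@dataclass(frozen=True)
class GaitParams:
    """Kinematic parameters of one synthetic walker.

    ``cadence`` is in single steps per second (a single step = half a gait
    cycle, so step duration in frames = fps / cadence); amplitudes are in
    pixels; ``conf_beta`` parametrizes the per-joint confidence Beta
    distribution; ``label`` is 0 = HC, 1 = PD.
    """

    cadence: float = 0.6
    stride_amp: float = 45.0
    step_len: float = 90.0
    sway_amp: float = 8.0
    tremor_sd: float = 0.6
    conf_beta: tuple[float, float] = (8.0, 1.0)
    stationary_pad: int = 60
    label: int = 0

    def __post_init__(self):
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if min(self.stride_amp, self.step_len, self.sway_amp, self.tremor_sd) < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Exact landing-frame boundaries and subject metadata of one recording."""

    true_boundaries: list[StepBoundary]
    label: int
    priors: PriorVector | None = None


@dataclass
class CohortData:
    recordings: list[DualViewRecording]
    truths: list[GroundTruth]
    priors: dict[str, PriorVector] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.truths])


# vertical body stack, pixels above the ground line (y grows downward)
_HEIGHTS = {
    "ankle": 0.0, "knee": 62.0, "hip": 125.0, "shoulder": 235.0,
    "elbow": 185.0, "wrist": 130.0, "nose": 295.0, "eye": 305.0, "ear": 300.0,
}
# COCO-17 order: nose, l_eye, r_eye, l_ear, r_ear, l_sho, r_sho, l_elb,
# r_elb, l_wri, r_wri, l_hip, r_hip, l_knee, r_knee, l_ank, r_ank


def _coco_frame_lateral(body_x, ground_y, lift_l, lift_r, swing_l, swing_r, bob):
    """One frame of sagittal-projection joint coordinates, (17, 2)."""
    pts = np.empty((17, 2))
    yb = ground_y - bob
    pts[0] = (body_x + 18, yb - _HEIGHTS["nose"])
    pts[1] = pts[2] = (body_x + 20, yb - _HEIGHTS["eye"])
    pts[3] = pts[4] = (body_x + 8, yb - _HEIGHTS["ear"])
    pts[5] = pts[6] = (body_x, yb - _HEIGHTS["shoulder"])
    # arms swing opposite to the ipsilateral leg
    pts[7] = (body_x - 0.3 * swing_l, yb - _HEIGHTS["elbow"])
    pts[8] = (body_x - 0.3 * swing_r, yb - _HEIGHTS["elbow"])
    pts[9] = (body_x - 0.5 * swing_l, yb - _HEIGHTS["wrist"])
    pts[10] = (body_x - 0.5 * swing_r, yb - _HEIGHTS["wrist"])
    pts[11] = pts[12] = (body_x, yb - _HEIGHTS["hip"])
    pts[13] = (body_x + 0.5 * swing_l, yb - _HEIGHTS["knee"] - 0.4 * lift_l)
    pts[14] = (body_x + 0.5 * swing_r, yb - _HEIGHTS["knee"] - 0.4 * lift_r)
    pts[15] = (body_x + swing_l, ground_y - lift_l)
    pts[16] = (body_x + swing_r, ground_y - lift_r)
    return pts


def _coco_frame_frontal(center_x, ground_y, lift_l, lift_r, sway, bob, scale):
    """One frame of coronal-projection coordinates with distance scale."""
    pts = np.empty((17, 2))
    cx = center_x + sway
    yb = ground_y - bob
    pts[0] = (cx, yb - _HEIGHTS["nose"])
    pts[1] = (cx - 10, yb - _HEIGHTS["eye"])
    pts[2] = (cx + 10, yb - _HEIGHTS["eye"])
    pts[3] = (cx - 18, yb - _HEIGHTS["ear"])
    pts[4] = (cx + 18, yb - _HEIGHTS["ear"])
    pts[5] = (cx - 42, yb - _HEIGHTS["shoulder"])
    pts[6] = (cx + 42, yb - _HEIGHTS["shoulder"])
    pts[7] = (cx - 52, yb - _HEIGHTS["elbow"])
    pts[8] = (cx + 52, yb - _HEIGHTS["elbow"])
    pts[9] = (cx - 56, yb - _HEIGHTS["wrist"])
    pts[10] = (cx + 56, yb - _HEIGHTS["wrist"])
    pts[11] = (cx - 28, yb - _HEIGHTS["hip"])
    pts[12] = (cx + 28, yb - _HEIGHTS["hip"])
    pts[13] = (cx - 24, yb - _HEIGHTS["knee"] - 0.4 * lift_l)
    pts[14] = (cx + 24, yb - _HEIGHTS["knee"] - 0.4 * lift_r)
    pts[15] = (cx - 20, ground_y - lift_l)
    pts[16] = (cx + 20, ground_y - lift_r)
    # subject approaches the frontal camera: scale about the image centre
    centre = np.array([_IMG_W / 2, _IMG_H / 2])
    return centre + scale * (pts - centre)


def synth_subject(
    params: GaitParams,
    duration: float = 20.0,
    seed: int = 0,
    subject_id: str = "S000",
    fps: float = FPS,
) -> tuple[DualViewRecording, GroundTruth]:
    """Generate one dual-view recording with exact landing-frame truth.

    ``duration`` is the walking time in seconds (stationary pads are
    appended on both sides); it must cover at least two gait cycles.
    """
    rng = np.random.default_rng(seed)
    f_cycle = params.cadence / 2.0  # gait cycles per second (2 steps/cycle)
    cycle_frames = fps / f_cycle
    n_walk = int(round(duration * fps))
    if n_walk < 2 * cycle_frames + 2:
        raise ValueError("duration must cover at least two gait cycles")
    pad = params.stationary_pad
    n_total = n_walk + 2 * pad

    t = np.arange(n_total, dtype=float)
    tw = np.clip(t - pad, 0.0, n_walk - 1)  # frozen posture inside the pads

    phi0 = 0.7 * np.pi  # start mid-descent so no landing falls on the pad edge
    phi_r = 2 * np.pi * f_cycle * tw / fps + phi0
    phi_l = phi_r - np.pi

    # initiation/termination envelope: half a cycle of ramp at either end
    ramp = 0.5 * cycle_frames
    env = np.clip(tw / ramp, 0.0, 1.0) * np.clip((n_walk - 1 - tw) / ramp, 0.0, 1.0)
    env = np.clip(env, 0.0, 1.0)
    in_pad = (t < pad) | (t >= pad + n_walk)
    env[in_pad] = 0.0

    # foot-lift profile: one ground contact per gait cycle with a sharp
    # final descent (|sin|^0.7 cusp), mimicking the fast approach of the
    # foot before heel strike; the landing frame is the cusp
    lift_r = params.stride_amp * env * np.abs(np.sin(phi_r / 2)) ** 0.7
    lift_l = params.stride_amp * env * np.abs(np.sin(phi_l / 2)) ** 0.7
    swing_r = 0.5 * params.step_len * env * np.sin(phi_r)
    swing_l = 0.5 * params.step_len * env * np.sin(phi_l)
    bob = 4.0 * env * np.sin(2 * phi_r)
    speed = params.step_len * params.cadence / fps  # px per frame
    body_x = 120.0 + speed * tw
    ground_y = 900.0
    sway = params.sway_amp * env * np.sin(phi_r)
    scale = 0.85 + 0.4 * tw / max(n_walk - 1, 1)

    lat = np.empty((n_total, 17, 3))
    fro = np.empty((n_total, 17, 3))
    for i in range(n_total):
        lat[i, :, :2] = _coco_frame_lateral(
            body_x[i], ground_y, lift_l[i], lift_r[i], swing_l[i], swing_r[i], bob[i]
        )
        fro[i, :, :2] = _coco_frame_frontal(
            _IMG_W / 2, ground_y, lift_l[i], lift_r[i], sway[i], bob[i], scale[i]
        )
    if params.tremor_sd > 0:
        lat[:, :, :2] += rng.normal(0, params.tremor_sd, size=(n_total, 17, 2))
        fro[:, :, :2] += rng.normal(0, params.tremor_sd, size=(n_total, 17, 2))
    a, b = params.conf_beta
    lat[:, :, 2] = rng.beta(a, b, size=(n_total, 17))
    fro[:, :, 2] = rng.beta(a, b, size=(n_total, 17))

    # exact landing frames: phases hitting 0 mod 2pi inside the full-envelope span
    def _landings(phi_offset: float) -> np.ndarray:
        # phase(tw) = 2 pi f_cycle tw / fps + phi0 - phi_offset = 2 pi k
        ks = np.arange(1, int(n_walk / cycle_frames) + 2)
        frames = (ks - (phi0 - phi_offset) / (2 * np.pi)) * cycle_frames
        frames = frames[(frames >= ramp) & (frames <= n_walk - 1 - ramp)]
        return np.round(frames).astype(int) + pad

    right_land = _landings(0.0)
    left_land = _landings(np.pi)
    boundaries = []
    for i, r in enumerate(right_land):
        nxt = right_land[i + 1] if i + 1 < right_land.size else np.inf
        after = left_land[(left_land > r) & (left_land < nxt)]
        if after.size:
            boundaries.append(StepBoundary(int(r), int(after[0])))

    lat_seq = KeypointSequence(subject_id, View.LATERAL, lat, fps=fps)
    fro_seq = KeypointSequence(subject_id, View.FRONTAL, fro, fps=fps)
    rec = make_dual_view_sample(fro_seq, lat_seq)
    truth = GroundTruth(true_boundaries=boundaries, label=params.label)
    return rec, truth


def _hc_params(rng: np.random.Generator) -> dict:
    return {
        "cadence": float(np.clip(rng.normal(0.62, 0.04), 0.45, 0.85)),
        "stride_amp": float(np.clip(rng.normal(45.0, 6.0), 20.0, 75.0)),
        "step_len": float(np.clip(rng.normal(90.0, 10.0), 50.0, 130.0)),
        "sway_amp": float(np.clip(rng.normal(8.0, 2.0), 2.0, 16.0)),
        "tremor_sd": float(abs(rng.normal(0.6, 0.2))),
    }


def _apply_effect(p: dict, effect: float, rng: np.random.Generator) -> dict:
    """Shift HC-drawn parameters toward the PD phenotype by `effect`."""
    q = dict(p)
    q["stride_amp"] = p["stride_amp"] * (1 - 0.45 * effect)
    q["step_len"] = p["step_len"] * (1 - 0.40 * effect)
    q["cadence"] = p["cadence"] * (1 - 0.10 * effect)
    q["tremor_sd"] = p["tremor_sd"] + 1.2 * effect
    q["sway_amp"] = p["sway_amp"] * (1 + 0.3 * effect)
    return q


def synth_cohort(
    n_subjects: int = 60,
    class_ratio: tuple[float, float] = (0.72, 0.28),
    effect_size: float = 1.0,
    seed: int = 0,
    duration: float = 20.0,
    stationary_pad: int = 60,
) -> CohortData:
    """Generate a cohort with class-dependent gait and correlated priors.

    ``effect_size`` scales every class difference (gait and priors); 0
    yields statistically identical classes (a null cohort). The realized
    class split is round(n * ratio), at least 2 per class.
    """
    rng = np.random.default_rng(seed)
    n_pd = int(np.clip(round(n_subjects * class_ratio[1] / sum(class_ratio)), 2,
                       n_subjects - 2))
    labels = np.array([1] * n_pd + [0] * (n_subjects - n_pd))
    rng.shuffle(labels)
    recordings, truths, priors = [], [], {}
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        srng = np.random.default_rng(child_seeds[i])
        base = _hc_params(srng)
        label = int(labels[i])
        pdict = _apply_effect(base, effect_size, srng) if label == 1 else base
        params = GaitParams(**pdict, stationary_pad=stationary_pad, label=label)
        rec, truth = synth_subject(
            params, duration=duration, seed=int(child_seeds[i]) + 7, subject_id=sid
        )
        sex = 1.0 if srng.random() < 0.5 else -1.0
        age = srng.normal(55.8, 9.2) + (6.9 * effect_size if label else 0.0)
        height = srng.normal(165.6, 7.2)
        weight = srng.normal(69.2, 11.9) - (2.9 * effect_size if label else 0.0)
        shoe = srng.normal(41.5 if sex > 0 else 37.5, 1.0)
        pv = PriorVector(
            sex=sex, age=float(age), height=float(height), weight=float(weight),
            shoe_size=float(shoe), step_duration=1.0 / params.cadence,
        )
        truth.priors = pv
        priors[sid] = pv
        recordings.append(rec)
        truths.append(truth)
    return CohortData(recordings=recordings, truths=truths, priors=priors)


def cohort_to_samples(
    cohort: CohortData,
    use_true_boundaries: bool = False,
    fp: FilterParams = FilterParams(),
    pp: PeakParams | None = None,
) -> list[StepSample]:
    """Segment and normalize a whole cohort into model-ready step samples.

    With ``use_true_boundaries`` the generator's exact landing frames are
    used instead of running the detector (isolates downstream stages).
    """
    samples: list[StepSample] = []
    for rec, truth in zip(cohort.recordings, cohort.truths):
        if use_true_boundaries:
            bounds = truth.true_boundaries
        else:
            bounds = extract_steps(rec, fp, pp)
        samples.extend(build_step_samples(rec, bounds, truth.label))
    return samples
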