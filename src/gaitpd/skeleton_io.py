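"""Keypoint-sequence I/O and joint-layout conventions.

A recording is a per-frame sequence of 2-D skeletal keypoints in COCO-17
order as emitted by an off-the-shelf pose estimator: for each frame, 17
joints with pixel x, pixel y and a confidence score in [0, 1]. Two file
dialects are supported — a flat CSV (header
``frame,j0_x,j0_y,j0_c,...,j16_c``) and an equivalent JSON-lines dialect
(one object per frame with keys ``frame`` and ``joints``).

Face keypoints other than the nose (both eyes, both ears) carry no gait
information and are dropped before analysis, leaving 13 joints; the reduced
order is frozen in :data:`REDUCED13_INDICES`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

COCO17_NAMES = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)

#: COCO-17 indices retained after dropping eyes and ears, in frozen order.
REDUCED13_INDICES = (0, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16)
REDUCED13_NAMES = tuple(COCO17_NAMES[i] for i in REDUCED13_INDICES)

# positions inside the reduced layout used downstream
R13_NOSE = 0
R13_LEFT_ANKLE = REDUCED13_NAMES.index("left_ankle")
R13_RIGHT_ANKLE = REDUCED13_NAMES.index("right_ankle")

PRIOR_FIELDS = ("sex", "age", "height", "weight", "bmi", "shoe_size", "step_duration")


class View(str, Enum):
    FRONTAL = "frontal"
    LATERAL = "lateral"


class JointLayout(str, Enum):
    COCO17 = "coco17"
    REDUCED13 = "reduced13"


_LAYOUT_SIZES = {JointLayout.COCO17: 17, JointLayout.REDUCED13: 13}


@dataclass
class KeypointSequence:
    """One view's raw per-frame joint coordinates and confidences.

    ``data`` has shape (n_frames, n_joints, 3) with channels (x, y, conf).
    """

    subject_id: str
    view: View
    data: np.ndarray
    fps: float = 30.0
    joint_layout: JointLayout = JointLayout.COCO17

    def __post_init__(self):
        self.view = View(self.view)
        self.joint_layout = JointLayout(self.joint_layout)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"keypoint data must be (frames, joints, 3), got {self.data.shape}")
        expected = _LAYOUT_SIZES[self.joint_layout]
        if self.data.shape[1] != expected:
            raise ValueError(
                f"layout {self.joint_layout.value} expects {expected} joints, "
                f"got {self.data.shape[1]}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        conf = self.data[:, :, 2]
        if np.any(conf < 0) or np.any(conf > 1):
            raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_joints(self) -> int:
        return self.data.shape[1]

    def x(self) -> np.ndarray:
        return self.data[:, :, 0]

    def y(self) -> np.ndarray:
        return self.data[:, :, 1]

    def conf(self) -> np.ndarray:
        return self.data[:, :, 2]


@dataclass
class DualViewRecording:
    """Temporally aligned frontal + lateral views of one walking bout."""

    frontal: KeypointSequence
    lateral: KeypointSequence

    def __post_init__(self):
        if self.frontal.subject_id != self.lateral.subject_id:
            raise ValueError("views belong to different subjects")
        if self.frontal.n_frames != self.lateral.n_frames:
            raise ValueError("views have different frame counts; use make_dual_view_sample")

    @property
    def subject_id(self) -> str:
        return self.frontal.subject_id

    @property
    def n_frames(self) -> int:
        return self.frontal.n_frames


@dataclass
class PriorVector:
    """Physiological priors for one subject.

    Sex is coded +1 male / -1 female; BMI is recomputed from height/weight
    (kg / m^2) when not supplied.
    """

    sex: float
    age: float
    height: float
    weight: float
    shoe_size: float
    step_duration: float
    bmi: float | None = field(default=None)

    def __post_init__(self):
        if self.sex not in (+1, -1):
            raise ValueError("sex must be +1 (male) or -1 (female)")
        if self.bmi is None:
            self.bmi = self.weight / (self.height / 100.0) ** 2

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PRIOR_FIELDS], dtype=float)


# --------------------------------------------------------------------- I/O

def _csv_columns(n_joints: int = 17) -> list[str]:
    cols = ["frame"]
    for j in range(n_joints):
        cols += [f"j{j}_x", f"j{j}_y", f"j{j}_c"]
    return cols


def _check_frames(frames: np.ndarray, path) -> None:
    diffs = np.diff(frames)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0)) + 1
        raise ValueError(f"{path}: frame index not strictly increasing at row {bad}")
    if np.any(diffs != 1):
        bad = int(np.argmax(diffs != 1)) + 1
        raise ValueError(f"{path}: gap in frame index at row {bad}")


def read_keypoint_file(
    path: str | Path,
    view: View | str,
    subject_id: str | None = None,
    fps: float = 30.0,
) -> KeypointSequence:
    """Read a COCO-17 keypoint file (CSV or JSON-lines, by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if subject_id is None:
        subject_id = path.stem
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        frames, rows = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    frames.append(int(obj["frame"]))
                    joints = np.asarray(obj["joints"], dtype=float)
                except (json.JSONDecodeError, KeyError, ValueError) as exc:
                    raise ValueError(f"{path}: malformed JSON-lines row at line {lineno}") from exc
                if joints.shape != (17, 3):
                    raise ValueError(
                        f"{path}: line {lineno} has joint array {joints.shape}, expected (17, 3)"
                    )
                rows.append(joints)
        if not rows:
            raise ValueError(f"{path}: empty keypoint file")
        _check_frames(np.asarray(frames), path)
        data = np.stack(rows)
    else:
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ValueError(f"{path}: could not parse CSV: {exc}") from exc
        expected = _csv_columns()
        if list(df.columns) != expected:
            raise ValueError(
                f"{path}: CSV header mismatch; expected 'frame,j0_x,j0_y,j0_c,...,j16_c' "
                f"({len(expected)} columns), got {len(df.columns)}"
            )
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
            raise ValueError(f"{path}: malformed row at line {bad}")
        _check_frames(df["frame"].to_numpy(), path)
        data = df.iloc[:, 1:].to_numpy(dtype=float).reshape(len(df), 17, 3)
    return KeypointSequence(subject_id=subject_id, view=View(view), data=data, fps=fps)


def write_keypoint_file(seq: KeypointSequence, path: str | Path) -> None:
    """Write a COCO-17 sequence to CSV or JSON-lines (by extension)."""
    path = Path(path)
    if seq.joint_layout is not JointLayout.COCO17:
        raise ValueError("only coco17 sequences are written to interchange files")
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with open(path, "w") as fh:
            for i in range(seq.n_frames):
                fh.write(json.dumps({"frame": i, "joints": seq.data[i].tolist()}) + "\n")
    else:
        flat = seq.data.reshape(seq.n_frames, -1)
        df = pd.DataFrame(flat, columns=_csv_columns()[1:])
        df.insert(0, "frame", np.arange(seq.n_frames))
        df.to_csv(path, index=False)


def read_priors_csv(path: str | Path) -> dict[str, PriorVector]:
    """Read a priors table (subject_id, sex, age, height, weight, bmi, shoe_size, step_duration)."""
    df = pd.read_csv(path)
    required = {"subject_id", *PRIOR_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: priors CSV missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["subject_id"])] = PriorVector(
            sex=float(row["sex"]), age=float(row["age"]), height=float(row["height"]),
            weight=float(row["weight"]), bmi=float(row["bmi"]),
            shoe_size=float(row["shoe_size"]), step_duration=float(row["step_duration"]),
        )
    return out


def write_priors_csv(priors: dict[str, PriorVector], path: str | Path) -> None:
    rows = [{"subject_id": sid, **dict(zip(PRIOR_FIELDS, pv.as_array()))}
            for sid, pv in priors.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


# -------------------------------------------------------------- operations

def select_joints(seq: KeypointSequence) -> KeypointSequence:
    """Project a COCO-17 sequence onto the 13 gait-relevant joints.

    Drops both eyes and both ears; the output order is
    :data:`REDUCED13_NAMES`. A no-op (with a warning) on already reduced
    input.
    """
    if seq.joint_layout is JointLayout.REDUCED13:
        warnings.warn("sequence already in reduced13 layout; select_joints is a no-op")
        return seq
    return KeypointSequence(
        subject_id=seq.subject_id,
        view=seq.view,
        data=seq.data[:, REDUCED13_INDICES, :],
        fps=seq.fps,
        joint_layout=JointLayout.REDUCED13,
    )


def make_dual_view_sample(
    frontal: KeypointSequence, lateral: KeypointSequence
) -> DualViewRecording:
    """Pair synchronized views, truncating both to the common frame count."""
    if frontal.subject_id != lateral.subject_id:
        raise ValueError(
            f"cannot pair views of subjects {frontal.subject_id!r} and {lateral.subject_id!r}"
        )
    if frontal.view is not View.FRONTAL or lateral.view is not View.LATERAL:
        raise ValueError("arguments must be (frontal, lateral) in that order")
    if frontal.fps != lateral.fps:
        raise ValueError("views recorded at different frame rates")
    n = min(frontal.n_frames, lateral.n_frames)

    def _trunc(seq: KeypointSequence) -> KeypointSequence:
        if seq.n_frames == n:
            return seq
        return KeypointSequence(seq.subject_id, seq.view, seq.data[:n], seq.fps, seq.joint_layout)

    return DualViewRecording(frontal=_trunc(frontal), lateral=_trunc(lateral))
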