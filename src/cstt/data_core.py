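"""Domain types and on-disk formats for care-annotated motion data.

A sample couples three modalities recorded in a long-term-care setting:

* a **skeleton sequence** — 17 COCO-convention 2-D body key points per frame
  with detection confidences (pixel coordinates, x right / y down);
* a **heatmap sequence** — one 64x64 single-channel depth heatmap per frame,
  values normalized to [0, 1];
* a **care record** — the subject's care level, an integer 1-5 assigned by
  medical professionals (1 = minimal assistance, 5 = maximum assistance),
  grouped into low (1-2), mid (3) and high (4-5) assistance requirement.

Activity labels are ``0 sitting, 1 eating, 2 stand up, 3 trying to stand
up``.  High-assistance subjects are predominantly immobile, so stand-up and
trying-to-stand-up samples never occur in the high group; this structural
property is validated on load.

On-disk layout under a dataset root::

    manifest.csv                      sample_id,subject_id,session_id,care_level,label
    keypoints/<sample_id>.csv         frame,joint,x,y,conf
    heatmaps/<sample_id>_<frame:05d>.png   16-bit grayscale, 64x64
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "COCO_JOINTS",
    "COCO_BONES",
    "ANGLE_TRIPLES",
    "ActivityLabel",
    "CareGroup",
    "SkeletonSequence",
    "HeatmapSequence",
    "CareRecord",
    "LabeledSample",
    "Dataset",
    "DatasetError",
    "care_group",
    "load_dataset",
    "save_dataset",
    "window_sample",
]

HEATMAP_SIZE = 64
N_JOINTS = 17

#: COCO-17 joint order.
COCO_JOINTS = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)

_J = {name: i for i, name in enumerate(COCO_JOINTS)}

#: Skeleton bones (joint-index pairs) used for rendering and joint angles.
COCO_BONES = (
    (_J["nose"], _J["left_eye"]), (_J["nose"], _J["right_eye"]),
    (_J["left_eye"], _J["left_ear"]), (_J["right_eye"], _J["right_ear"]),
    (_J["left_shoulder"], _J["right_shoulder"]),
    (_J["left_shoulder"], _J["left_elbow"]), (_J["left_elbow"], _J["left_wrist"]),
    (_J["right_shoulder"], _J["right_elbow"]), (_J["right_elbow"], _J["right_wrist"]),
    (_J["left_shoulder"], _J["left_hip"]), (_J["right_shoulder"], _J["right_hip"]),
    (_J["left_hip"], _J["right_hip"]),
    (_J["left_hip"], _J["left_knee"]), (_J["left_knee"], _J["left_ankle"]),
    (_J["right_hip"], _J["right_knee"]), (_J["right_knee"], _J["right_ankle"]),
)

#: (parent, joint, child) triples defining the interior angle at ``joint``
#: between the bone vectors joint->parent and joint->child.  Only joints with
#: two incident bones along a limb chain carry a defined angle; the other
#: joints (nose, eyes, ears, wrists, ankles) are masked NaN.
ANGLE_TRIPLES = (
    (_J["left_hip"], _J["left_shoulder"], _J["left_elbow"]),
    (_J["right_hip"], _J["right_shoulder"], _J["right_elbow"]),
    (_J["left_shoulder"], _J["left_elbow"], _J["left_wrist"]),
    (_J["right_shoulder"], _J["right_elbow"], _J["right_wrist"]),
    (_J["left_shoulder"], _J["left_hip"], _J["left_knee"]),
    (_J["right_shoulder"], _J["right_hip"], _J["right_knee"]),
    (_J["left_hip"], _J["left_knee"], _J["left_ankle"]),
    (_J["right_hip"], _J["right_knee"], _J["right_ankle"]),
)


class ActivityLabel(enum.IntEnum):
    SITTING = 0
    EATING = 1
    STAND_UP = 2
    TRYING_TO_STAND_UP = 3


class CareGroup(str, enum.Enum):
    LOW = "low"
    MID = "mid"
    HIGH = "high"


#: Labels structurally absent from the high-assistance group.
HIGH_GROUP_FORBIDDEN = frozenset(
    {ActivityLabel.STAND_UP, ActivityLabel.TRYING_TO_STAND_UP}
)


def care_group(care_level: int) -> CareGroup:
    """Map a care level 1-5 onto its assistance-requirement group."""
    if care_level in (1, 2):
        return CareGroup.LOW
    if care_level == 3:
        return CareGroup.MID
    if care_level in (4, 5):
        return CareGroup.HIGH
    raise ValueError(f"care level must be in 1..5, got {care_level}")


class DatasetError(ValueError):
    """Raised for invalid datasets; carries an itemized per-sample report."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("dataset validation failed:\n" + "\n".join(self.errors))


@dataclasses.dataclass
class SkeletonSequence:
    """Per-frame 17-joint 2-D key points with confidences."""

    keypoints: np.ndarray  # (T_f, 17, 2), pixels
    confidences: np.ndarray  # (T_f, 17), in [0, 1]

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        self.confidences = np.asarray(self.confidences, dtype=np.float64)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (N_JOINTS, 2):
            raise ValueError(f"keypoints must be (T_f, 17, 2), got {self.keypoints.shape}")
        if self.keypoints.shape[0] < 1:
            raise ValueError("a skeleton sequence needs at least one frame")
        if self.confidences.shape != self.keypoints.shape[:2]:
            raise ValueError("confidences must be (T_f, 17)")
        if not np.all(np.isfinite(self.keypoints)):
            raise ValueError("keypoint coordinates must be finite")
        if np.any(self.confidences < 0) or np.any(self.confidences > 1):
            raise ValueError("confidences must lie in [0, 1]")

    @property
    def frames(self) -> int:
        return self.keypoints.shape[0]


@dataclasses.dataclass
class HeatmapSequence:
    """Per-frame 64x64 normalized depth heatmaps."""

    maps: np.ndarray  # (T_f, 64, 64), in [0, 1]; float32 (16-bit on disk)

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float32)
        if self.maps.ndim != 3 or self.maps.shape[1:] != (HEATMAP_SIZE, HEATMAP_SIZE):
            raise ValueError(f"maps must be (T_f, 64, 64), got {self.maps.shape}")
        if np.any(self.maps < 0) or np.any(self.maps > 1) or not np.all(np.isfinite(self.maps)):
            raise ValueError("heatmap values must lie in [0, 1]")

    @property
    def frames(self) -> int:
        return self.maps.shape[0]


@dataclasses.dataclass(frozen=True)
class CareRecord:
    subject_id: str
    care_level: int

    def __post_init__(self):
        care_group(self.care_level)  # range check

    @property
    def group(self) -> CareGroup:
        return care_group(self.care_level)


@dataclasses.dataclass
class LabeledSample:
    """One labeled motion clip: skeleton + heatmaps + care context."""

    sample_id: str
    skeleton: SkeletonSequence
    heatmaps: HeatmapSequence
    care: CareRecord
    label: ActivityLabel
    session_id: str

    def __post_init__(self):
        self.label = ActivityLabel(self.label)
        if self.skeleton.frames != self.heatmaps.frames:
            raise ValueError(
                f"sample {self.sample_id}: skeleton has {self.skeleton.frames} frames "
                f"but heatmaps have {self.heatmaps.frames}"
            )
        if self.care.group is CareGroup.HIGH and self.label in HIGH_GROUP_FORBIDDEN:
            raise ValueError(
                f"sample {self.sample_id}: high-assistance subjects cannot carry "
                f"label {self.label.name}"
            )

    @property
    def frames(self) -> int:
        return self.skeleton.frames


class Dataset:
    """Ordered collection of labeled samples with a metadata manifest."""

    def __init__(self, samples: list[LabeledSample]):
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[LabeledSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> LabeledSample:
        return self.samples[i]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject_id": [s.care.subject_id for s in self.samples],
                "session_id": [s.session_id for s in self.samples],
                "care_level": [s.care.care_level for s in self.samples],
                "label": [int(s.label) for s in self.samples],
            }
        )

    def sessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.session_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# I/O

_MANIFEST_COLS = ["sample_id", "subject_id", "session_id", "care_level", "label"]


def save_dataset(d: Dataset, root_path: str | Path) -> Path:
    """Write a dataset to ``root_path``; returns the manifest path.

    The byte layout is deterministic for identical input: floats are printed
    with the shortest round-tripping repr and heatmaps quantized to 16 bits.
    """
    root = Path(root_path)
    (root / "keypoints").mkdir(parents=True, exist_ok=True)
    (root / "heatmaps").mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.csv"
    d.manifest.to_csv(manifest_path, index=False)
    for s in d.samples:
        t_f = s.frames
        frame_idx = np.repeat(np.arange(t_f), N_JOINTS)
        joint_idx = np.tile(np.arange(N_JOINTS), t_f)
        kp = s.skeleton.keypoints.reshape(-1, 2)
        conf = s.skeleton.confidences.reshape(-1)
        df = pd.DataFrame(
            {"frame": frame_idx, "joint": joint_idx,
             "x": kp[:, 0], "y": kp[:, 1], "conf": conf}
        )
        df.to_csv(root / "keypoints" / f"{s.sample_id}.csv", index=False,
                  float_format="%.17g")
        for t in range(t_f):
            arr = np.round(s.heatmaps.maps[t] * 65535.0).astype(np.uint16)
            Image.fromarray(arr).save(
                root / "heatmaps" / f"{s.sample_id}_{t:05d}.png"
            )
    return manifest_path


def _load_sample(root: Path, row: pd.Series) -> LabeledSample:
    sid = str(row["sample_id"])
    kp_path = root / "keypoints" / f"{sid}.csv"
    if not kp_path.exists():
        raise ValueError(f"sample {sid}: missing keypoint file {kp_path.name}")
    df = pd.read_csv(kp_path, float_precision="round_trip")
    t_f = int(df["frame"].max()) + 1
    if len(df) != t_f * N_JOINTS:
        raise ValueError(f"sample {sid}: keypoint file has {len(df)} rows, "
                         f"expected {t_f * N_JOINTS}")
    df = df.sort_values(["frame", "joint"], kind="stable")
    kp = df[["x", "y"]].to_numpy().reshape(t_f, N_JOINTS, 2)
    conf = df["conf"].to_numpy().reshape(t_f, N_JOINTS)
    maps = []
    for t in range(t_f):
        hm_path = root / "heatmaps" / f"{sid}_{t:05d}.png"
        if not hm_path.exists():
            raise ValueError(
                f"sample {sid}: skeleton has {t_f} frames but heatmap frame "
                f"{t} is missing"
            )
        maps.append(np.asarray(Image.open(hm_path), dtype=np.float64) / 65535.0)
    care_level = int(row["care_level"])
    if not 1 <= care_level <= 5:
        raise ValueError(f"sample {sid}: care_level {care_level} outside 1..5")
    return LabeledSample(
        sample_id=sid,
        skeleton=SkeletonSequence(kp, conf),
        heatmaps=HeatmapSequence(np.stack(maps) if maps else np.zeros((0, 64, 64))),
        care=CareRecord(str(row["subject_id"]), care_level),
        label=ActivityLabel(int(row["label"])),
        session_id=str(row["session_id"]),
    )


def load_dataset(root_path: str | Path) -> Dataset:
    """Load a dataset, validating every invariant; raises :class:`DatasetError`
    with an itemized report if any sample is malformed."""
    root = Path(root_path)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_COLS if c not in manifest.columns]
    if missing:
        raise DatasetError([f"manifest missing columns: {missing}"])
    samples: list[LabeledSample] = []
    errors: list[str] = []
    for _, row in manifest.iterrows():
        try:
            samples.append(_load_sample(root, row))
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise DatasetError(errors)
    return Dataset(samples)


# ---------------------------------------------------------------------------
# Windowing

def window_sample(s: LabeledSample, window_len: int, stride: int) -> list[LabeledSample]:
    """Cut a sample into fixed-length windows inheriting label, care, session.

    Returns ``floor((T_f - window_len)/stride) + 1`` windows, or an empty
    list when the clip is shorter than the window.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    t_f = s.frames
    if t_f < window_len:
        return []
    out = []
    for w, start in enumerate(range(0, t_f - window_len + 1, stride)):
        sl = slice(start, start + window_len)
        out.append(
            LabeledSample(
                sample_id=f"{s.sample_id}_w{w:03d}",
                skeleton=SkeletonSequence(
                    s.skeleton.keypoints[sl].copy(), s.skeleton.confidences[sl].copy()
                ),
                heatmaps=HeatmapSequence(s.heatmaps.maps[sl].copy()),
                care=s.care,
                label=s.label,
                session_id=s.session_id,
            )
        )
    return out
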