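"""Care-conditioned synthetic motion generator.

The care-facility recordings this package is designed for cannot be shared,
so this module fabricates datasets with the same statistical structure: four
seated-context activities (sitting, eating, stand up, trying to stand up),
care levels 1-5 whose posture effects grow with assistance need, absence of
stand-up-type activities in the high-assistance group, strong motion overlap
between eating and trying-to-stand (both involve leaning forward and
extending the hands), and class imbalance with trying-to-stand rarest.

Skeletons are drawn from hand-designed parametric archetypes in a virtual
640x640-pixel frame (frontal camera view, origin top-left, y down); depth
heatmaps are rendered from the skeleton as Gaussian joint blobs plus limb
segments on a 64x64 canvas (one tenth of the virtual frame).  Everything is
deterministic given the spec seed: each (subject, class, sample) gets its own
named random stream derived from the master seed, so adding samples never
perturbs existing ones.

Care-level modulation of posture (generator defaults, not measured values):
movement amplitude is scaled by ``1 - 0.15*(care_level - 1)`` and a forward
lean of ``0.08*(care_level - 1)`` radians is applied to the upper body, so
higher assistance need means smaller, more hunched movements.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .data_core import (
    ANGLE_TRIPLES,  # noqa: F401  (re-exported convenience)
    COCO_BONES,
    COCO_JOINTS,
    ActivityLabel,
    CareGroup,
    CareRecord,
    Dataset,
    HeatmapSequence,
    LabeledSample,
    SkeletonSequence,
    care_group,
)

__all__ = [
    "SubjectProfile",
    "GeneratorSpec",
    "generate_subject",
    "generate_sample",
    "generate_dataset",
    "render_heatmap",
    "separable_spec",
    "interaction_spec",
]

_J = {name: i for i, name in enumerate(COCO_JOINTS)}

VIRTUAL_FRAME = 640.0  # virtual camera frame, pixels
CANVAS_SCALE = 0.1  # virtual pixels -> 64x64 canvas pixels

#: Care-level distribution mirroring the study cohort's group proportions
#: (low 35.3%, mid 51.0%, high 13.7% of 51 participants), with the low and
#: high shares split evenly over their two levels.
DEFAULT_CARE_DISTRIBUTION = (0.18, 0.173, 0.51, 0.07, 0.067)

#: Default per-subject sample counts; trying-to-stand is rarest, matching the
#: natural imbalance of the activity in care facilities.
DEFAULT_COUNTS: dict[ActivityLabel, int] = {
    ActivityLabel.SITTING: 4,
    ActivityLabel.EATING: 4,
    ActivityLabel.STAND_UP: 2,
    ActivityLabel.TRYING_TO_STAND_UP: 1,
}
#: High-assistance subjects are predominantly immobile: sitting/eating only.
DEFAULT_HIGH_COUNTS: dict[ActivityLabel, int] = {
    ActivityLabel.SITTING: 4,
    ActivityLabel.EATING: 4,
}

_FORBIDDEN_HIGH = (ActivityLabel.STAND_UP, ActivityLabel.TRYING_TO_STAND_UP)


# ---------------------------------------------------------------------------
# Base poses and activity archetypes

def _seated_pose() -> np.ndarray:
    """Canonical seated pose, virtual-frame pixels, person centered."""
    p = np.zeros((17, 2))
    p[_J["nose"]] = (320, 200)
    p[_J["left_eye"]] = (310, 190)
    p[_J["right_eye"]] = (330, 190)
    p[_J["left_ear"]] = (300, 198)
    p[_J["right_ear"]] = (340, 198)
    p[_J["left_shoulder"]] = (268, 280)
    p[_J["right_shoulder"]] = (372, 280)
    p[_J["left_elbow"]] = (252, 345)
    p[_J["right_elbow"]] = (388, 345)
    p[_J["left_wrist"]] = (258, 405)
    p[_J["right_wrist"]] = (382, 405)
    p[_J["left_hip"]] = (285, 405)
    p[_J["right_hip"]] = (355, 405)
    p[_J["left_knee"]] = (272, 480)
    p[_J["right_knee"]] = (368, 480)
    p[_J["left_ankle"]] = (268, 565)
    p[_J["right_ankle"]] = (372, 565)
    return p


def _standing_pose() -> np.ndarray:
    """Fully risen pose reached at the end of a stand-up."""
    p = _seated_pose().copy()
    rise = 130.0
    for name in ("nose", "left_eye", "right_eye", "left_ear", "right_ear",
                 "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
                 "left_wrist", "right_wrist", "left_hip", "right_hip"):
        p[_J[name], 1] -= rise
    p[_J["left_knee"], 1] -= 55.0
    p[_J["right_knee"], 1] -= 55.0
    # arms hang down when standing
    p[_J["left_wrist"]] = p[_J["left_elbow"]] + (-4.0, 62.0)
    p[_J["right_wrist"]] = p[_J["right_elbow"]] + (4.0, 62.0)
    return p


_UPPER = [_J[n] for n in ("nose", "left_eye", "right_eye", "left_ear", "right_ear",
                          "left_shoulder", "right_shoulder", "left_elbow",
                          "right_elbow", "left_wrist", "right_wrist")]


def _logistic(u: float, center: float = 0.5, width: float = 0.08) -> float:
    return 1.0 / (1.0 + np.exp(-(u - center) / width))


def _sitting(u: float, amplitude: float) -> np.ndarray:
    """Static seated pose; frame-to-frame variation comes from tremor only."""
    return _seated_pose().copy()


def _eating(u: float, amplitude: float) -> np.ndarray:
    """Feeding motion: the trunk hovers forward over the tray with both hands
    extended while the right wrist cycles to the mouth.

    The sustained lean and hand extension make eating resemble the early
    phase of trying to stand — the overlap that motivates care-aware
    modeling — while differing strongly from upright, static sitting.
    """
    p = _seated_pose().copy()
    # sustained hover over the table, shared with trying-to-stand
    hover = amplitude * min(1.0, 0.25 + u * 3.0)  # settles quickly, then holds
    lean_drop = 50.0 * hover
    for j in _UPPER:
        p[j, 1] += lean_drop * (1.0 - (p[j, 1] - 200.0) / 210.0)
    extend = 56.0 * hover
    p[_J["left_wrist"]] += (-0.35 * extend, -0.8 * extend)
    p[_J["right_wrist"]] += (0.35 * extend, -0.8 * extend)
    # cyclic bite: right wrist to the mouth and back, twice per clip
    phase = 0.5 * (1.0 - np.cos(2.0 * np.pi * 2.0 * u))
    reach = amplitude * phase
    wrist0 = p[_J["right_wrist"]].copy()
    near_mouth = p[_J["nose"]] + (18.0, 28.0)
    p[_J["right_wrist"]] = wrist0 + reach * (near_mouth - wrist0)
    elbow0 = p[_J["right_elbow"]].copy()
    p[_J["right_elbow"]] = elbow0 + reach * np.array((-12.0, -48.0))
    return p


def _trying_to_stand(u: float, amplitude: float) -> np.ndarray:
    """Forward lean with a partial hip rise and hands extended for support."""
    p = _seated_pose().copy()
    effort = _logistic(u, center=0.3, width=0.1)
    rise = 0.45 * amplitude * effort  # never completes the rise
    seated, standing = _seated_pose(), _standing_pose()
    p = p + rise * (standing - seated)
    # pronounced forward lean of the trunk and head, matching the hover
    # posture of eating -- the source of the real-world confusion
    lean_drop = 50.0 * amplitude * effort
    for j in _UPPER:
        p[j, 1] += lean_drop * (1.0 - (p[j, 1] - 200.0) / 210.0)
    # hands push forward/outward seeking support
    extend = 56.0 * amplitude * effort
    p[_J["left_wrist"]] += (-0.35 * extend, -0.8 * extend)
    p[_J["right_wrist"]] += (0.35 * extend, -0.8 * extend)
    return p


def _stand_up(u: float, amplitude: float) -> np.ndarray:
    """Full sit-to-stand transition with hip and knee extension."""
    seated, standing = _seated_pose(), _standing_pose()
    rise = amplitude * _logistic(u, center=0.5, width=0.1)
    return seated + rise * (standing - seated)


_ARCHETYPES = {
    ActivityLabel.SITTING: _sitting,
    ActivityLabel.EATING: _eating,
    ActivityLabel.STAND_UP: _stand_up,
    ActivityLabel.TRYING_TO_STAND_UP: _trying_to_stand,
}

#: The two activities whose motion patterns overlap in practice.
_CONFUSABLE = (ActivityLabel.EATING, ActivityLabel.TRYING_TO_STAND_UP)


# ---------------------------------------------------------------------------
# Subjects

@dataclasses.dataclass(frozen=True)
class SubjectProfile:
    """A synthetic subject: care record plus posture modifiers.

    ``lean_angle`` (radians) and ``amplitude`` (unitless scale) modulate every
    archetype; ``confusability`` in [0, 1] blends eating and trying-to-stand
    toward each other for mid-group subjects; ``swap_confusable`` swaps the
    two archetypes outright (used to build datasets whose labels depend on
    the care x motion interaction).
    """

    care: CareRecord
    lean_angle: float
    amplitude: float
    tremor_sd: float
    confusability: float = 0.0
    swap_confusable: bool = False

    def __post_init__(self):
        if self.amplitude < 0 or self.tremor_sd < 0:
            raise ValueError("amplitude and tremor_sd must be >= 0")


def _stream(*key: int) -> np.random.Generator:
    """Named random stream: a Generator keyed by integers off the master seed."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(list(key))))


def generate_subject(
    care_level: int,
    seed: int,
    *,
    subject_id: str | None = None,
    tremor_sd: float = 2.0,
    confusability: float = 0.0,
    amp_slope: float = 0.15,
    lean_slope: float = 0.08,
    swap_confusable: bool = False,
) -> SubjectProfile:
    """Draw a subject at the given care level.

    For a fixed seed the modifiers are monotone in care level: the lean angle
    is non-decreasing and the movement amplitude non-increasing as the level
    rises, reflecting progressively hunched posture and reduced mobility.
    """
    group = care_group(care_level)  # validates the range
    rng = _stream(seed, 0xC0FFEE)
    z_lean, z_amp = rng.standard_normal(2)
    lean = max(0.0, lean_slope * (care_level - 1) + 0.015 * z_lean)
    amplitude = max(0.1, 1.0 - amp_slope * (care_level - 1)) * float(np.exp(0.06 * z_amp))
    return SubjectProfile(
        care=CareRecord(subject_id or f"subj{seed:05d}", care_level),
        lean_angle=lean,
        amplitude=amplitude,
        tremor_sd=tremor_sd,
        confusability=confusability if group is CareGroup.MID else 0.0,
        swap_confusable=swap_confusable and group is CareGroup.MID,
    )


def _apply_lean(p: np.ndarray, lean_angle: float) -> np.ndarray:
    """Hunch the upper body forward about the hip line.

    In the frontal view a sagittal forward lean compresses the apparent
    height of the trunk (cosine foreshortening) and drifts the head slightly
    sideways toward the table edge.
    """
    if lean_angle <= 0:
        return p
    q = p.copy()
    hip_y = 0.5 * (p[_J["left_hip"], 1] + p[_J["right_hip"], 1])
    drop = 1.0 - np.cos(lean_angle)
    drift = 0.35 * np.sin(lean_angle)
    for j in _UPPER:
        height = hip_y - p[j, 1]
        q[j, 1] += height * drop
        q[j, 0] += height * drift
    return q


def generate_sample(
    subject: SubjectProfile,
    activity: ActivityLabel,
    t_f: int,
    seed: int,
    *,
    sample_id: str = "sample",
    session_id: str = "s00",
) -> LabeledSample:
    """Synthesize one labeled clip for a subject.

    High-group subjects are predominantly immobile, so requesting stand-up or
    trying-to-stand for them is an error (those activities are absent from
    the high group).
    """
    activity = ActivityLabel(activity)
    if subject.care.group is CareGroup.HIGH and activity in _FORBIDDEN_HIGH:
        raise ValueError(
            f"activity {activity.name} does not occur in the high-assistance group"
        )
    if t_f < 1:
        raise ValueError("t_f must be >= 1")
    rng = _stream(seed, int(activity), 0x5A17)

    primary = _ARCHETYPES[activity]
    blend_partner = None
    lam = 0.0
    if activity in _CONFUSABLE:
        other = _CONFUSABLE[1 - _CONFUSABLE.index(activity)]
        if subject.swap_confusable:
            primary, blend_partner = _ARCHETYPES[other], None
        elif subject.confusability > 0:
            blend_partner = _ARCHETYPES[other]
            lam = 0.5 * subject.confusability

    kp = np.empty((t_f, 17, 2))
    for t in range(t_f):
        u = t / max(t_f - 1, 1)
        pose = primary(u, subject.amplitude)
        if blend_partner is not None:
            pose = (1.0 - lam) * pose + lam * blend_partner(u, subject.amplitude)
        kp[t] = _apply_lean(pose, subject.lean_angle)
    if subject.tremor_sd > 0:
        kp = kp + rng.normal(0.0, subject.tremor_sd, size=kp.shape)
    kp = np.clip(kp, 8.0, VIRTUAL_FRAME - 8.0)

    conf = 0.75 + 0.25 * rng.random((t_f, 17))
    maps = np.stack([render_heatmap(kp[t]) for t in range(t_f)])
    return LabeledSample(
        sample_id=sample_id,
        skeleton=SkeletonSequence(kp, conf),
        heatmaps=HeatmapSequence(maps),
        care=subject.care,
        label=activity,
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# Heatmap rendering

def render_heatmap(
    frame_keypoints: np.ndarray,
    *,
    size: int = 64,
    scale: float = CANVAS_SCALE,
    blob_sigma: float = 1.6,
    limb_sigma: float = 1.1,
    bones: tuple[tuple[int, int], ...] = COCO_BONES,
) -> np.ndarray:
    """Render a stylized depth heatmap from one frame of key points.

    The map is a sum of isotropic Gaussian blobs at the (scaled) joint
    locations plus Gaussian-profile limb segments between topologically
    adjacent joints, normalized so the brightest pixel is 1.  Purely
    deterministic.  Each kernel is only evaluated inside a local crop of
    ~4 sigma around its support, which keeps rendering cheap.
    """
    pts = np.asarray(frame_keypoints, dtype=np.float64) * scale
    out = np.zeros((size, size))

    def _accumulate_gauss(dist2: np.ndarray, sigma: float,
                          y0: int, y1: int, x0: int, x1: int) -> None:
        out[y0:y1, x0:x1] += np.exp(-0.5 * dist2 / (sigma * sigma))

    def _crop(lo_x, hi_x, lo_y, hi_y, margin):
        x0 = max(int(np.floor(lo_x - margin)), 0)
        x1 = min(int(np.ceil(hi_x + margin)) + 1, size)
        y0 = max(int(np.floor(lo_y - margin)), 0)
        y1 = min(int(np.ceil(hi_y + margin)) + 1, size)
        return x0, x1, y0, y1

    for px, py in pts:
        x0, x1, y0, y1 = _crop(px, px, py, py, 4.0 * blob_sigma)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        _accumulate_gauss(d2, blob_sigma, y0, y1, x0, x1)

    for a, b in bones:
        pa, pb = pts[a], pts[b]
        x0, x1, y0, y1 = _crop(min(pa[0], pb[0]), max(pa[0], pb[0]),
                               min(pa[1], pb[1]), max(pa[1], pb[1]),
                               4.0 * limb_sigma)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        seg = pb - pa
        seg_len2 = float(seg @ seg)
        if seg_len2 < 1e-12:
            d2 = (xx - pa[0]) ** 2 + (yy - pa[1]) ** 2
        else:
            t = ((xx - pa[0]) * seg[0] + (yy - pa[1]) * seg[1]) / seg_len2
            t = np.clip(t, 0.0, 1.0)
            d2 = (xx - (pa[0] + t * seg[0])) ** 2 + (yy - (pa[1] + t * seg[1])) ** 2
        _accumulate_gauss(d2, limb_sigma, y0, y1, x0, x1)

    peak = out.max()
    if peak > 0:
        out /= peak
    return out


# ---------------------------------------------------------------------------
# Dataset generation

@dataclasses.dataclass
class GeneratorSpec:
    """Everything that determines a synthetic dataset.

    ``samples_per_subject_per_class`` applies to low/mid subjects;
    ``high_samples_per_subject_per_class`` to high-assistance subjects and
    must not request stand-up-type activities.
    """

    n_subjects: int = 30
    care_level_distribution: tuple[float, ...] = DEFAULT_CARE_DISTRIBUTION
    samples_per_subject_per_class: Mapping[ActivityLabel, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    high_samples_per_subject_per_class: Mapping[ActivityLabel, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_HIGH_COUNTS)
    )
    frames_per_sample: int = 32
    n_sessions: int = 5
    seed: int = 0
    tremor_sd: float = 2.0
    confusability: float = 0.6
    amp_slope: float = 0.15
    lean_slope: float = 0.08
    interaction: bool = False

    def validate(self) -> None:
        dist = np.asarray(self.care_level_distribution, dtype=float)
        if dist.shape != (5,) or np.any(dist < 0) or not np.isclose(dist.sum(), 1.0):
            raise ValueError("care_level_distribution must be 5 probabilities summing to 1")
        for counts in (self.samples_per_subject_per_class,
                       self.high_samples_per_subject_per_class):
            if any(c < 0 for c in counts.values()):
                raise ValueError("sample counts must be >= 0")
        for lbl in _FORBIDDEN_HIGH:
            if self.high_samples_per_subject_per_class.get(lbl, 0) > 0:
                raise ValueError(
                    "impossible spec: high-assistance subjects cannot perform "
                    f"{ActivityLabel(lbl).name}"
                )
        if self.n_subjects < 0 or self.frames_per_sample < 1 or self.n_sessions < 2:
            raise ValueError("need n_subjects >= 0, frames >= 1, n_sessions >= 2")


def generate_dataset(spec: GeneratorSpec) -> Dataset:
    """Generate a full dataset honoring the spec counts.

    Each sample of a subject is assigned to one of ``n_sessions`` global
    recording sessions (days); a subject with at least two samples is
    guaranteed to appear in at least two sessions so a cross-day split is
    meaningful.  Determinism: every (subject, class, sample) triple draws
    from its own stream keyed off ``spec.seed``.
    """
    spec.validate()
    dist = np.asarray(spec.care_level_distribution, dtype=float)
    samples: list[LabeledSample] = []
    for i in range(spec.n_subjects):
        subj_rng = _stream(spec.seed, 1, i)
        care_level = int(subj_rng.choice(5, p=dist)) + 1
        subject = generate_subject(
            care_level,
            seed=spec.seed * 100_003 + i,
            subject_id=f"subj{i:03d}",
            tremor_sd=spec.tremor_sd,
            confusability=spec.confusability,
            amp_slope=spec.amp_slope,
            lean_slope=spec.lean_slope,
            swap_confusable=spec.interaction,
        )
        counts = (spec.high_samples_per_subject_per_class
                  if subject.care.group is CareGroup.HIGH
                  else spec.samples_per_subject_per_class)
        sessions = subj_rng.permutation(spec.n_sessions)
        k = 0
        for lbl in sorted(counts, key=int):
            for rep in range(counts[lbl]):
                # first two samples land in distinct sessions by construction
                session = int(sessions[k % spec.n_sessions])
                sid = f"subj{i:03d}_{ActivityLabel(lbl).name.lower()}_{rep:02d}"
                samples.append(
                    generate_sample(
                        subject,
                        ActivityLabel(lbl),
                        spec.frames_per_sample,
                        seed=_sample_seed(spec.seed, i, int(lbl), rep),
                        sample_id=sid,
                        session_id=f"day{session:02d}",
                    )
                )
                k += 1
    return Dataset(samples)


def _sample_seed(master: int, subject: int, label: int, rep: int) -> int:
    """Stable per-sample seed: mixing is positional, so inserting new samples
    elsewhere never changes an existing stream."""
    return ((master * 1_000_003 + subject) * 101 + label) * 1009 + rep


def separable_spec(n_subjects: int = 30, seed: int = 0) -> GeneratorSpec:
    """Zero-noise, fully separable world: distinct archetypes, no tremor.

    A nearest-centroid classifier on flattened keypoints solves this world
    perfectly within each care group; it is the sanity ceiling for training.
    """
    return GeneratorSpec(
        n_subjects=n_subjects, seed=seed, tremor_sd=0.0, confusability=0.0,
        frames_per_sample=24,
    )


def interaction_spec(n_subjects: int = 12, seed: int = 0) -> GeneratorSpec:
    """World where the label depends on the care x motion interaction.

    Mid-group subjects perform the eating and trying-to-stand archetypes
    swapped relative to low-group subjects, while the care-dependent posture
    modulation is switched off — so the motion alone is ambiguous between
    the two classes and only the care level disambiguates them.  A care-blind
    model cannot exceed chance on the confusable pair; a care-aware one can.
    """
    balanced = {
        ActivityLabel.SITTING: 2,
        ActivityLabel.EATING: 3,
        ActivityLabel.STAND_UP: 2,
        ActivityLabel.TRYING_TO_STAND_UP: 3,
    }
    return GeneratorSpec(
        n_subjects=n_subjects,
        care_level_distribution=(0.25, 0.25, 0.5, 0.0, 0.0),
        samples_per_subject_per_class=balanced,
        frames_per_sample=24,
        seed=seed,
        tremor_sd=1.5,
        confusability=0.0,
        amp_slope=0.0,
        lean_slope=0.0,
        interaction=True,
    )
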