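"""Motion-similarity statistics for dataset validation.

Three complementary statistics quantify how similar two motion sequences (or
pools of sequences) are:

* **MPJAD** — mean per-joint angle difference: the average absolute
  difference of joint angles between two skeleton sequences over their common
  frames and the joints for which an angle is defined.  Lower = more
  similar.
* **Cosine dissimilarity** — ``1 - cos`` between flattened keypoint
  sequences; the within-class mean over pairs measures class homogeneity
  (lower = more homogeneous).
* **HOG similarity** — cosine similarity between histogram-of-oriented-
  gradients descriptors of two depth heatmaps; 1 means near-identical
  gradient structure.

Joint angles are defined at each joint between its inbound and outbound bone
vectors under the COCO-17 topology (shoulders, elbows, hips, knees); joints
with fewer than two incident limb bones (nose, eyes, ears, wrists, ankles)
are masked NaN and excluded, with renormalization, from every average.

The module also assembles the pairwise group/activity similarity tables used
to demonstrate that motion patterns depend on care level: cells where the
high-assistance group lacks an activity are structurally N/A.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from skimage.feature import hog as _skimage_hog

from .data_core import (
    ANGLE_TRIPLES,
    ActivityLabel,
    CareGroup,
    Dataset,
    LabeledSample,
    SkeletonSequence,
)

__all__ = [
    "JointAngleSequence",
    "SimilarityTable",
    "joint_angles",
    "mpjad_pair",
    "mpjad_set",
    "cosine_dissimilarity",
    "mean_pairwise_cosine_dissimilarity",
    "hog_features",
    "hog_similarity",
    "build_similarity_tables",
]

#: Canonical HOG configuration: 8x8-pixel cells, 2x2-cell blocks, 9 unsigned
#: orientation bins, L2-Hys block normalization.
HOG_PARAMS = dict(
    orientations=9,
    pixels_per_cell=(8, 8),
    cells_per_block=(2, 2),
    block_norm="L2-Hys",
    feature_vector=True,
)


@dataclasses.dataclass
class JointAngleSequence:
    """Per-frame joint angles in radians, NaN where undefined."""

    angles: np.ndarray  # (T_f, 17)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 2 or self.angles.shape[1] != 17:
            raise ValueError("angles must be (T_f, 17)")
        defined = self.angles[~np.isnan(self.angles)]
        if np.any(defined < -1e-9) or np.any(defined > np.pi + 1e-9):
            raise ValueError("defined joint angles must lie in [0, pi]")

    @property
    def frames(self) -> int:
        return self.angles.shape[0]


def joint_angles(s: SkeletonSequence,
                 triples: tuple[tuple[int, int, int], ...] = ANGLE_TRIPLES
                 ) -> JointAngleSequence:
    """Interior angle at each joint between its two incident bone vectors.

    For a triple (parent, joint, child) the angle is ``arccos`` of the
    normalized dot product of ``parent - joint`` and ``child - joint``
    (so a straight limb gives pi).  Joints without a triple, or frames where
    a bone degenerates to zero length, yield NaN.
    """
    kp = s.keypoints  # (T_f, 17, 2)
    out = np.full((kp.shape[0], 17), np.nan)
    for parent, joint, child in triples:
        v1 = kp[:, parent] - kp[:, joint]
        v2 = kp[:, child] - kp[:, joint]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        ok = (n1 > 1e-12) & (n2 > 1e-12)
        cosang = np.full(kp.shape[0], np.nan)
        cosang[ok] = np.clip(
            np.einsum("td,td->t", v1, v2)[ok] / (n1[ok] * n2[ok]), -1.0, 1.0
        )
        out[:, joint] = np.arccos(cosang)
    return JointAngleSequence(out)


def mpjad_pair(a: JointAngleSequence, b: JointAngleSequence) -> float:
    """Mean absolute joint-angle difference over common frames and defined
    joints (masked entries are excluded and the denominator renormalized)."""
    t_common = min(a.frames, b.frames)
    if t_common < 1:
        raise ValueError("sequences share no common frames")
    diff = np.abs(a.angles[:t_common] - b.angles[:t_common])
    mask = ~np.isnan(diff)
    if not mask.any():
        raise ValueError("no jointly defined angles between the sequences")
    return float(diff[mask].mean())


def mpjad_set(sequences: list[JointAngleSequence]) -> float:
    """Mean of :func:`mpjad_pair` over all unordered pairs of sequences."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    vals = [mpjad_pair(a, b) for a, b in itertools.combinations(sequences, 2)]
    return float(np.mean(vals))


def _flatten_motion(s: SkeletonSequence, t_common: int | None = None) -> np.ndarray:
    kp = s.keypoints if t_common is None else s.keypoints[:t_common]
    return kp.reshape(-1)


def cosine_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - cos`` angle between two flattened motion vectors; in [0, 2]."""
    a = np.asarray(a, dtype=np.float64).reshape(-1)
    b = np.asarray(b, dtype=np.float64).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("motion vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine dissimilarity undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def mean_pairwise_cosine_dissimilarity(class_sequences: list[SkeletonSequence]) -> float:
    """Within-class homogeneity: mean cosine dissimilarity over all unordered
    pairs of member sequences, truncated to the common minimum length."""
    if len(class_sequences) < 2:
        raise ValueError("need at least two class members")
    t_min = min(s.frames for s in class_sequences)
    vecs = [_flatten_motion(s, t_min) for s in class_sequences]
    vals = [cosine_dissimilarity(a, b) for a, b in itertools.combinations(vecs, 2)]
    return float(np.mean(vals))


def hog_features(img: np.ndarray) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor of a 64x64 map."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    return _skimage_hog(img, **HOG_PARAMS)


def hog_similarity(img1: np.ndarray, img2: np.ndarray) -> float:
    """Cosine similarity between the HOG descriptors of two images.

    A constant image has no gradients, hence a zero descriptor, and its
    similarity is undefined: that case raises rather than returning a number.
    """
    h1, h2 = hog_features(img1), hog_features(img2)
    n1, n2 = np.linalg.norm(h1), np.linalg.norm(h2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("HOG similarity undefined: constant (gradient-free) image")
    return float((h1 @ h2) / (n1 * n2))


# ---------------------------------------------------------------------------
# Pairwise similarity tables

_ACTIVITY_SHORT = {
    ActivityLabel.EATING: "E",
    ActivityLabel.SITTING: "S",
    ActivityLabel.TRYING_TO_STAND_UP: "T",
    ActivityLabel.STAND_UP: "SU",
}
_GROUP_PAIRS = (
    (CareGroup.LOW, CareGroup.HIGH),
    (CareGroup.HIGH, CareGroup.MID),
    (CareGroup.MID, CareGroup.LOW),
)


@dataclasses.dataclass
class SimilarityTable:
    """Three aligned layers of a pairwise similarity table (NaN = N/A)."""

    mpjad: pd.DataFrame
    cosine: pd.DataFrame
    hog: pd.DataFrame

    def to_csv(self, path) -> None:
        layers = {"MPJAD": self.mpjad, "cosine_dissimilarity": self.cosine,
                  "HOG_similarity": self.hog}
        combined = pd.concat(layers, names=["statistic"])
        combined.to_csv(path, float_format="%.4f", na_rep="N/A")


def _mean_heatmap(s: LabeledSample) -> np.ndarray:
    return s.heatmaps.maps.mean(axis=0)


def _cross_pair_stats(pool_a: list[LabeledSample], pool_b: list[LabeledSample],
                      max_pool: int) -> tuple[float, float, float]:
    """Average the three statistics over cross pairs of the two pools."""
    pool_a = pool_a[:max_pool]
    pool_b = pool_b[:max_pool]
    ang_a = [joint_angles(s.skeleton) for s in pool_a]
    ang_b = [joint_angles(s.skeleton) for s in pool_b]
    hm_a = [_mean_heatmap(s) for s in pool_a]
    hm_b = [_mean_heatmap(s) for s in pool_b]
    mpjads, cosines, hogs = [], [], []
    for i, sa in enumerate(pool_a):
        for j, sb in enumerate(pool_b):
            mpjads.append(mpjad_pair(ang_a[i], ang_b[j]))
            t_min = min(sa.frames, sb.frames)
            cosines.append(cosine_dissimilarity(
                _flatten_motion(sa.skeleton, t_min), _flatten_motion(sb.skeleton, t_min)
            ))
            try:
                hogs.append(hog_similarity(hm_a[i], hm_b[j]))
            except ValueError:
                pass
    hog_val = float(np.mean(hogs)) if hogs else np.nan
    return float(np.mean(mpjads)), float(np.mean(cosines)), hog_val


def build_similarity_tables(
    d: Dataset,
    mode: str = "by_care_group",
    *,
    max_pool: int = 12,
    normalize: bool = False,
) -> SimilarityTable:
    """Assemble the pairwise similarity table for a dataset.

    ``by_care_group``: for each activity, the three statistics between
    care-group pools (columns L-H, H-M, M-L); N/A where the high group lacks
    the activity.  ``by_activity_within_groups``: all 12 ordered activity
    pairs, first activity from the mid pool, second from the low pool.

    Statistics are raw values; ``normalize=True`` applies an optional min-max
    rescaling of each finite layer to [0, 1] (for comparability of reported
    scales, off by default).  ``max_pool`` caps each pool for tractability.
    """
    by_key: dict[tuple[CareGroup, ActivityLabel], list[LabeledSample]] = {}
    for s in d:
        by_key.setdefault((s.care.group, s.label), []).append(s)

    def cell(pool_a, pool_b, name):
        if not pool_a or not pool_b:
            warnings.warn(f"empty pool for cell {name}; reporting N/A")
            return (np.nan, np.nan, np.nan)
        return _cross_pair_stats(pool_a, pool_b, max_pool)

    if mode == "by_care_group":
        rows = [ActivityLabel.EATING, ActivityLabel.SITTING,
                ActivityLabel.TRYING_TO_STAND_UP, ActivityLabel.STAND_UP]
        cols = [f"{a.value[0].upper()}-{b.value[0].upper()}" for a, b in _GROUP_PAIRS]
        layers = np.full((3, len(rows), len(cols)), np.nan)
        for r, act in enumerate(rows):
            for c, (ga, gb) in enumerate(_GROUP_PAIRS):
                layers[:, r, c] = cell(
                    by_key.get((ga, act), []), by_key.get((gb, act), []),
                    f"{_ACTIVITY_SHORT[act]}:{cols[c]}",
                )
        index = [_ACTIVITY_SHORT[a] for a in rows]
    elif mode == "by_activity_within_groups":
        acts = [ActivityLabel.EATING, ActivityLabel.SITTING,
                ActivityLabel.TRYING_TO_STAND_UP, ActivityLabel.STAND_UP]
        pairs = [(a, b) for a in acts for b in acts if a != b]
        layers = np.full((3, len(pairs), 1), np.nan)
        for r, (act_mid, act_low) in enumerate(pairs):
            layers[:, r, 0] = cell(
                by_key.get((CareGroup.MID, act_mid), []),
                by_key.get((CareGroup.LOW, act_low), []),
                f"{_ACTIVITY_SHORT[act_mid]}-{_ACTIVITY_SHORT[act_low]}",
            )
        index = [f"{_ACTIVITY_SHORT[a]}-{_ACTIVITY_SHORT[b]}" for a, b in pairs]
        cols = ["mid-low"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if normalize:
        for k in range(3):
            layer = layers[k]
            finite = np.isfinite(layer)
            if finite.any() and np.ptp(layer[finite]) > 0:
                lo, hi = layer[finite].min(), layer[finite].max()
                layers[k] = (layer - lo) / (hi - lo)

    frames = [pd.DataFrame(layers[k], index=index, columns=cols) for k in range(3)]
    return SimilarityTable(mpjad=frames[0], cosine=frames[1], hog=frames[2])
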