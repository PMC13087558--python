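"""Classification metrics and diagnostics for the activity recognizer.

Covers the full evaluation surface: per-class and macro precision / recall /
F1 and accuracy, one-vs-rest ROC curves with per-class, micro and macro
AUCs, per-class cumulative-gain curves, row-normalized confusion matrices
overall and per care group, and the care-query attention-weight matrix that
shows how the care level steers attention between the keypoint token and the
heatmap patches.

Conventions: predictions are the argmax of the probabilities with the lowest
class index winning exact ties; classes absent from the ground truth are
reported as NaN and excluded from macro averages (the high-assistance group
structurally lacks the stand-up classes); ROC ties are rank-averaged, so the
trapezoidal AUC equals the pair-counting definition.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_curve

from .model import CSTTConfig, MODES, ModelMode, forward_batch

__all__ = [
    "EvalReport",
    "predict_labels",
    "classification_metrics",
    "roc_auc_ovr",
    "cumulative_gain",
    "confusion_by_group",
    "export_attention_matrix",
    "evaluate_model",
]

N_CLASSES = 4

#: Evaluation forward passes run in chunks of this many windows so the
#: intermediate activation graph of a large test set never lives at once.
EVAL_CHUNK = 64


def _forward_chunked(params, config, windows, mode) -> tuple[np.ndarray, np.ndarray, list]:
    """Forward all windows in chunks; returns (probs, cam_weights, groups)."""
    probs, cam = [], []
    token_groups: list = []
    for start in range(0, len(windows), EVAL_CHUNK):
        sub = windows.subset(np.arange(start, min(start + EVAL_CHUNK, len(windows))))
        p, diag = forward_batch(
            params, config, sub.keypoints, sub.heatmaps, sub.care_levels,
            mode=mode, mask_seeds=sub.mask_seeds,
        )
        probs.append(p.data.copy())
        cam.append(diag["cam_attention"])
        token_groups = diag["token_groups"]
    return np.concatenate(probs), np.concatenate(cam), token_groups


def predict_labels(y_prob: np.ndarray) -> np.ndarray:
    """Argmax prediction; exact ties go to the lowest class index."""
    return np.argmax(y_prob, axis=-1)


def _check_probs(y_prob: np.ndarray) -> np.ndarray:
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_prob.ndim != 2:
        raise ValueError("y_prob must be (n_samples, n_classes)")
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return y_prob


def classification_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict:
    """Per-class and macro precision/recall/F1 plus accuracy.

    A class absent from ``y_true`` has undefined recall: it is reported as
    NaN and excluded from the macro averages.
    """
    y_true = np.asarray(y_true)
    y_prob = _check_probs(y_prob)
    y_pred = predict_labels(y_prob)
    present = np.unique(y_true)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=present, zero_division=0
        )
    per_class = {}
    for k in range(N_CLASSES):
        if k in present:
            i = int(np.where(present == k)[0][0])
            per_class[k] = {"precision": float(prec[i]), "recall": float(rec[i]),
                            "f1": float(f1[i]), "support": int(support[i])}
        else:
            per_class[k] = {"precision": np.nan, "recall": np.nan,
                            "f1": np.nan, "support": 0}
    macro = {
        "precision": float(np.mean(prec)),
        "recall": float(np.mean(rec)),
        "f1": float(np.mean(f1)),
    }
    return {
        "per_class": per_class,
        "macro": macro,
        "accuracy": float(np.mean(y_pred == y_true)),
    }


def roc_auc_ovr(y_true: np.ndarray, y_prob: np.ndarray) -> dict:
    """One-vs-rest trapezoidal AUC per class, plus micro and macro averages.

    Micro pools all (sample, class) binary decisions; macro is the
    unweighted mean over classes with both positives and negatives; a
    degenerate class is NaN.
    """
    y_true = np.asarray(y_true)
    y_prob = _check_probs(y_prob)
    per_class: dict[int, float] = {}
    for k in range(y_prob.shape[1]):
        pos = y_true == k
        if pos.all() or not pos.any():
            per_class[k] = np.nan
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), y_prob[:, k])
        per_class[k] = float(_sk_auc(fpr, tpr))
    onehot = np.eye(y_prob.shape[1])[y_true].ravel()
    fpr, tpr, _ = roc_curve(onehot, y_prob.ravel())
    defined = [v for v in per_class.values() if np.isfinite(v)]
    return {
        "per_class": per_class,
        "micro": float(_sk_auc(fpr, tpr)),
        "macro": float(np.mean(defined)) if defined else np.nan,
    }


def cumulative_gain(y_true: np.ndarray, y_prob: np.ndarray, class_k: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-all cumulative-gain curve for class ``class_k``.

    Samples are sorted by descending predicted probability of the class; the
    curve gives the fraction of that class's positives captured within the
    top fraction of samples inspected (baseline = diagonal).  Returns
    ``(x, y)`` points starting at (0, 0).
    """
    y_true = np.asarray(y_true)
    y_prob = _check_probs(y_prob)
    pos = (y_true == class_k).astype(float)
    n_pos = pos.sum()
    if n_pos == 0:
        raise ValueError(f"class {class_k} has no positive samples")
    order = np.argsort(-y_prob[:, class_k], kind="stable")
    captured = np.concatenate([[0.0], np.cumsum(pos[order]) / n_pos])
    inspected = np.arange(len(y_true) + 1) / len(y_true)
    return inspected, captured


def confusion_by_group(y_true: np.ndarray, y_pred: np.ndarray,
                       groups: np.ndarray) -> dict:
    """Row-normalized confusion matrices, overall and per care group.

    Rows for classes that never occur in a group are structurally absent and
    reported as NaN rows, alongside the list of absent classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    groups = np.asarray(groups)
    if not (len(y_true) == len(y_pred) == len(groups)):
        raise ValueError("y_true, y_pred and groups must align")

    def normalized(t, p):
        cm = _sk_confusion(t, p, labels=np.arange(N_CLASSES)).astype(float)
        row_sums = cm.sum(axis=1)
        out = np.full_like(cm, np.nan)
        nz = row_sums > 0
        out[nz] = cm[nz] / row_sums[nz, None]
        return out, [int(k) for k in np.flatnonzero(~nz)]

    overall, absent = normalized(y_true, y_pred)
    result = {"overall": {"matrix": overall, "absent_classes": absent}}
    for g in dict.fromkeys(groups):
        sel = groups == g
        if not sel.any():
            warnings.warn(f"care group {g!r} is empty; omitted")
            continue
        m, a = normalized(y_true[sel], y_pred[sel])
        result[str(g)] = {"matrix": m, "absent_classes": a}
    return result


def export_attention_matrix(
    params: dict,
    config: CSTTConfig,
    windows,
    mode: ModelMode | str = "cstt",
) -> tuple[np.ndarray, list[int], list[str]]:
    """Mean care-query attention per token group, per care level.

    Returns ``(matrix, care_levels, group_names)`` where row ``i`` holds the
    average attention weight mass the care query of level ``care_levels[i]``
    puts on each token group (keypoint token vs heatmap patches); rows sum
    to 1.  Only defined for care-aware modes.
    """
    mode = MODES[mode] if isinstance(mode, str) else mode
    if not mode.care_query:
        raise ValueError("attention export requires a care-aware (CSTT) mode")
    _, w, groups = _forward_chunked(params, config, windows, mode)
    token_groups = np.asarray(groups)  # w: (B, T, h, n_tok)
    group_names = list(dict.fromkeys(token_groups))
    levels = sorted(set(int(c) for c in windows.care_levels))
    matrix = np.zeros((len(levels), len(group_names)))
    for i, lvl in enumerate(levels):
        sel = windows.care_levels == lvl
        mean_w = w[sel].mean(axis=(0, 1, 2))  # (n_tok,)
        for j, g in enumerate(group_names):
            matrix[i, j] = mean_w[token_groups == g].sum()
    return matrix, levels, group_names


@dataclasses.dataclass
class EvalReport:
    """Aggregate evaluation output for one trained model."""

    metrics: dict
    auc: dict
    gains: dict[int, tuple[np.ndarray, np.ndarray]]
    confusion: dict
    attention: tuple[np.ndarray, list[int], list[str]] | None

    def to_json_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {str(k): clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.ndarray):
                return clean(x.tolist())
            if isinstance(x, (np.floating, float)):
                return None if not np.isfinite(x) else float(x)
            if isinstance(x, (np.integer, int)):
                return int(x)
            return x

        return clean({
            "metrics": self.metrics,
            "auc": self.auc,
            "gains": {k: {"inspected": v[0], "captured": v[1]}
                      for k, v in self.gains.items()},
            "confusion": self.confusion,
            "attention": None if self.attention is None else {
                "matrix": self.attention[0],
                "care_levels": self.attention[1],
                "token_groups": self.attention[2],
            },
        })


def evaluate_model(params: dict, config: CSTTConfig, windows,
                   mode: ModelMode | str = "cstt") -> EvalReport:
    """Full evaluation of a trained model on pre-cut windows."""
    mode_obj = MODES[mode] if isinstance(mode, str) else mode
    y_prob, _, _ = _forward_chunked(params, config, windows, mode_obj)
    y_pred = predict_labels(y_prob)
    gains = {}
    for k in np.unique(windows.labels):
        gains[int(k)] = cumulative_gain(windows.labels, y_prob, int(k))
    attention = None
    if mode_obj.care_query:
        attention = export_attention_matrix(params, config, windows, mode_obj)
    return EvalReport(
        metrics=classification_metrics(windows.labels, y_prob),
        auc=roc_auc_ovr(windows.labels, y_prob),
        gains=gains,
        confusion=confusion_by_group(windows.labels, y_pred, windows.groups),
        attention=attention,
    )
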