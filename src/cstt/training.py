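"""Optimization loop, cross-day splitting, and ablation orchestration.

The experimental protocol trains on windows cut from continuous clips and
benchmarks with a **cross-day split**: whole recording sessions (days) are
assigned to either the train or the test side, so no session leaks across.
The published deployment hyperparameters are the defaults: batch size 8,
initial learning rate 0.001, weight decay 0.0005, 25 epochs.  No class
rebalancing is applied — the natural imbalance (trying-to-stand rarest) is
part of the problem.  The loss is unweighted cross-entropy and the optimizer
Adam with decoupled weight decay at a constant rate.

Determinism: the (dataset seed, split seed, init seed) triple fully
determines the result on a single thread.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .autograd import AdamW, Tensor
from .data_core import Dataset, LabeledSample, window_sample
from .model import CSTTConfig, MODES, ModelMode, forward_batch, init_params

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "Windows",
    "TrainResult",
    "ABLATION_MODES",
    "prepare_windows",
    "make_split",
    "train",
    "run_ablation",
]

#: Ablation rows: public name -> model mode key.
ABLATION_MODES: dict[str, str] = {
    "TSTT (S+D)": "tstt",
    "TSTT (S+D+C)": "tstt+c",
    "CSTT (S+C)": "s+c",
    "CSTT (Sp+C)": "sp+c",
    "CSTT (D+C)": "d+c",
    "CSTT (Sp+D+C)": "sp+d+c",
    "CSTT (S+D+C)": "cstt",
}


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 0.001
    weight_decay: float = 0.0005
    epochs: int = 25
    seed: int = 0
    split_fraction: float = 0.8
    window_stride: int = 8
    precision: str = "float32"  # training dtype; inference accepts either

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if min(self.batch_size, self.epochs, self.window_stride) < 1:
            raise ValueError("batch_size, epochs and window_stride must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    train_sessions: tuple[str, ...]
    test_sessions: tuple[str, ...]

    def __post_init__(self):
        if set(self.train_sessions) & set(self.test_sessions):
            raise ValueError("train and test sessions must be disjoint")


@dataclasses.dataclass
class Windows:
    """Stacked fixed-length windows ready for batched forward passes."""

    keypoints: np.ndarray  # (N, T, 17, 2)
    heatmaps: np.ndarray  # (N, T, 64, 64)
    care_levels: np.ndarray  # (N,)
    labels: np.ndarray  # (N,)
    sessions: np.ndarray  # (N,) str
    groups: np.ndarray  # (N,) str — care group names
    mask_seeds: np.ndarray  # (N,) stable per-window seeds for joint masking

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "Windows":
        return Windows(*(getattr(self, f.name)[idx] for f in dataclasses.fields(self)))


def prepare_windows(d: Dataset, window: int, stride: int) -> Windows:
    wins: list[LabeledSample] = []
    for s in d:
        wins.extend(window_sample(s, window, stride))
    if not wins:
        raise ValueError("dataset yields no windows at this window length")
    return Windows(
        keypoints=np.stack([w.skeleton.keypoints for w in wins]),
        heatmaps=np.stack([w.heatmaps.maps for w in wins]),
        care_levels=np.array([w.care.care_level for w in wins]),
        labels=np.array([int(w.label) for w in wins]),
        sessions=np.array([w.session_id for w in wins]),
        groups=np.array([w.care.group.value for w in wins]),
        mask_seeds=np.array([zlib.crc32(w.sample_id.encode()) & 0x7FFFFFFF
                             for w in wins]),
    )


def make_split(d: Dataset, cfg: TrainConfig) -> SplitPlan:
    """Assign whole sessions greedily toward the target train fraction.

    Sessions are shuffled by the seed (breaking size ties deterministically),
    then sorted by size and assigned, largest first, to whichever side has
    the larger remaining deficit relative to its target sample count.
    """
    counts = d.manifest.groupby("session_id").size()
    sessions = list(counts.index)
    if len(sessions) < 2:
        raise ValueError("cross-day split needs at least 2 sessions")
    rng = np.random.default_rng(cfg.seed)
    order = [sessions[i] for i in rng.permutation(len(sessions))]
    order.sort(key=lambda s: -counts[s])  # stable: ties stay shuffled
    total = counts.sum()
    train_target = cfg.split_fraction * total
    test_target = total - train_target
    train, test = [], []
    n_train = n_test = 0
    for s in order:
        if train_target - n_train >= test_target - n_test:
            train.append(s)
            n_train += counts[s]
        else:
            test.append(s)
            n_test += counts[s]
    if not test:
        test.append(train.pop())
    if not train:
        train.append(test.pop())
    return SplitPlan(tuple(train), tuple(test))


@dataclasses.dataclass
class TrainResult:
    params: dict[str, Tensor]
    loss_log: list[float]
    split: SplitPlan
    model_config: CSTTConfig
    mode: str


def _cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.zeros(probs.shape, dtype=probs.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    picked = (probs * Tensor(onehot)).sum(axis=-1)
    return -((picked + 1e-12).log().mean())


def train(
    d: Dataset | Windows,
    model_cfg: CSTTConfig | None = None,
    train_cfg: TrainConfig | None = None,
    mode: ModelMode | str = "cstt",
    split: SplitPlan | None = None,
) -> TrainResult:
    """Train one model; returns the weights and the per-epoch mean loss log.

    ``d`` may be a full :class:`Dataset` (windows are cut and split here) or
    pre-cut :class:`Windows` restricted to the train side (then ``split``
    must be supplied for the record).
    """
    model_cfg = model_cfg or CSTTConfig()
    train_cfg = train_cfg or TrainConfig()
    mode_name = mode if isinstance(mode, str) else mode.name
    if isinstance(d, Dataset):
        split = split or make_split(d, train_cfg)
        windows = prepare_windows(d, model_cfg.window, train_cfg.window_stride)
        train_idx = np.isin(windows.sessions, split.train_sessions)
        assert not (set(split.train_sessions) & set(split.test_sessions))
        train_win = windows.subset(train_idx)
    else:
        if split is None:
            raise ValueError("pre-cut windows require an explicit split plan")
        train_win = d
    if len(train_win) == 0:
        raise ValueError("empty train split")

    params = init_params(model_cfg, seed=train_cfg.seed)
    if train_cfg.precision == "float32":
        for p in params.values():
            p.data = p.data.astype(np.float32)
    trainable = sorted(params)  # stable order for the optimizer state
    opt = AdamW([params[k] for k in trainable], lr=train_cfg.learning_rate,
                weight_decay=train_cfg.weight_decay)
    shuffle_rng = np.random.default_rng(train_cfg.seed + 1)
    dropout_rng = np.random.default_rng(train_cfg.seed + 2)
    loss_log: list[float] = []
    n = len(train_win)
    for _ in range(train_cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            batch = train_win.subset(idx)
            probs, _ = forward_batch(
                params, model_cfg, batch.keypoints, batch.heatmaps,
                batch.care_levels, mode=mode, rng=dropout_rng,
                mask_seeds=batch.mask_seeds,
            )
            loss = _cross_entropy(probs, batch.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        loss_log.append(float(np.mean(epoch_losses)))
    return TrainResult(params=params, loss_log=loss_log, split=split,
                       model_config=model_cfg, mode=mode_name)


def run_ablation(
    d: Dataset,
    modes: list[str] | None = None,
    model_cfg: CSTTConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train and evaluate each ablation variant on the same split and seeds.

    ``modes`` may use the public row names (``"CSTT (S+D+C)"``) or the mode
    keys (``"cstt"``); one row of macro precision/recall/F1 and accuracy per
    mode, all sharing the identical cross-day split and seed.
    """
    from .evaluate import _forward_chunked, classification_metrics  # local: avoid cycle

    model_cfg = model_cfg or CSTTConfig()
    train_cfg = train_cfg or TrainConfig()
    modes = list(modes or ABLATION_MODES)
    split = make_split(d, train_cfg)
    windows = prepare_windows(d, model_cfg.window, train_cfg.window_stride)
    train_win = windows.subset(np.isin(windows.sessions, split.train_sessions))
    test_win = windows.subset(np.isin(windows.sessions, split.test_sessions))
    rows = []
    for name in modes:
        key = ABLATION_MODES.get(name, name)
        if key not in MODES:
            raise ValueError(f"unknown ablation mode {name!r}")
        result = train(train_win, model_cfg, train_cfg, mode=key, split=split)
        probs, _, _ = _forward_chunked(result.params, model_cfg, test_win, key)
        metrics = classification_metrics(test_win.labels, probs)
        rows.append({
            "mode": name,
            "precision": metrics["macro"]["precision"],
            "recall": metrics["macro"]["recall"],
            "f1": metrics["macro"]["f1"],
            "accuracy": metrics["accuracy"],
        })
    return pd.DataFrame(rows).set_index("mode")
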