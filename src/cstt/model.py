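"""Care-assessment-aware spatiotemporal transformer (CSTT).

The network classifies a fixed-length window of motion into four activities
(sitting, eating, stand up, trying to stand up) from three heterogeneous
inputs: 17 2-D body key points per frame, a 64x64 depth heatmap per frame,
and the subject's scalar care level.

Per frame, the three modalities are embedded into a shared latent space of
dimension ``d``: the key points are flattened to 34 values and linearly
projected; the heatmap passes through a convolution and is cut into
non-overlapping patches, each linearly projected to a token; the care level
is rescaled to [-1, 1] and linearly projected.  The **care-aware attention
mechanism (CAM)** then uses the care embedding as the *sole query* of a
multi-head scaled-dot-product attention whose keys and values are the
concatenated keypoint + heatmap tokens — so the care context decides which
body parts and image regions matter.  A residual feed-forward block refines
the attended frame feature.  Sinusoidal positional encoding is added over
the frame axis and a standard pre-norm transformer encoder models temporal
dependencies; mean pooling and a softmax classifier produce class
probabilities.

The care-blind baseline (**TSTT**) replaces the care query with a learned,
care-independent query token; ablation modes drop the keypoint or heatmap
token sets or mask a random subset of joints ("partial skeleton").

Everything runs on NumPy via :mod:`cstt.autograd`; a full-precision forward
pass on a CPU is exact and deterministic.
"""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import yaml

from .autograd import Tensor, concat, conv2d
from .data_core import LabeledSample

__all__ = [
    "CSTTConfig",
    "ModelMode",
    "MODES",
    "FrameTokens",
    "init_params",
    "normalize_keypoints",
    "embed_keypoints",
    "embed_heatmap",
    "embed_care_level",
    "scaled_dot_attention",
    "care_aware_attention",
    "multihead_care_attention",
    "feedforward",
    "positional_encoding",
    "temporal_encode",
    "mean_pool",
    "classify",
    "forward_batch",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
    "parameter_count",
]

CHECKPOINT_SCHEMA = "cstt-checkpoint-v1"
N_JOINTS = 17
HEATMAP_SIZE = 64


@dataclasses.dataclass(frozen=True)
class CSTTConfig:
    """Architectural hyperparameters.

    ``pe_constant`` is the sinusoidal positional-encoding base (10,000).
    Defaults keep the model small enough to train on one CPU.
    """

    latent_dim: int = 64
    n_heads: int = 4
    n_temporal_layers: int = 2
    ffn_hidden: int = 128
    n_classes: int = 4
    window: int = 16
    heatmap_patch: int = 8
    conv_channels: int = 2
    dropout: float = 0.1
    pe_constant: float = 10_000.0
    frame_size: float = 640.0
    partial_mask_rate: float = 0.3

    def __post_init__(self):
        if self.latent_dim % self.n_heads != 0:
            raise ValueError("latent_dim must be divisible by n_heads")
        if self.pe_constant <= 0 or self.n_classes < 2:
            raise ValueError("pe_constant must be > 0 and n_classes >= 2")
        if HEATMAP_SIZE % self.heatmap_patch != 0:
            raise ValueError("heatmap_patch must divide 64")

    @property
    def n_patches(self) -> int:
        return (HEATMAP_SIZE // self.heatmap_patch) ** 2


@dataclasses.dataclass(frozen=True)
class ModelMode:
    """Which inputs are wired in and how the attention query is built."""

    name: str
    use_skeleton: bool = True
    use_heatmap: bool = True
    care_query: bool = True  # care embedding as the attention query (CAM)
    care_token: bool = False  # care embedding appended to the key/value set
    partial_skeleton: bool = False

    def __post_init__(self):
        if not (self.use_skeleton or self.use_heatmap):
            raise ValueError("at least one of skeleton/heatmap must be enabled")
        if self.partial_skeleton and not self.use_skeleton:
            raise ValueError("partial skeleton requires the skeleton input")
        if self.care_query and self.care_token:
            raise ValueError("care is either the query or a key/value token, not both")


#: Named modes matching the ablation variants.
MODES: dict[str, ModelMode] = {
    "cstt": ModelMode("cstt"),  # CSTT (S + D + C), the full model
    "tstt": ModelMode("tstt", care_query=False),  # TSTT (S + D), care-blind
    "tstt+c": ModelMode("tstt+c", care_query=False, care_token=True),  # TSTT (S + D + C)
    "s+c": ModelMode("s+c", use_heatmap=False),  # CSTT (S + C)
    "sp+c": ModelMode("sp+c", use_heatmap=False, partial_skeleton=True),  # CSTT (Sp + C)
    "d+c": ModelMode("d+c", use_skeleton=False),  # CSTT (D + C)
    "sp+d+c": ModelMode("sp+d+c", partial_skeleton=True),  # CSTT (Sp + D + C)
}


@dataclasses.dataclass
class FrameTokens:
    """Token sets of one frame: the query plus the key/value collection."""

    query: Tensor  # (..., 1, d) — care embedding (CSTT) or learned token (TSTT)
    keyvalue: Tensor  # (..., n_tokens, d) — concatenated keypoint/heatmap tokens


# ---------------------------------------------------------------------------
# Parameters

def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_params(config: CSTTConfig, seed: int = 0) -> dict[str, Tensor]:
    """Glorot-uniform initialization of every learnable weight."""
    rng = np.random.default_rng(seed)
    d, h = config.latent_dim, config.ffn_hidden
    c, k = config.conv_channels, 3
    patch_dim = config.conv_channels * config.heatmap_patch ** 2

    def lin(fan_in, fan_out):
        return Tensor(_linear_init(rng, fan_in, fan_out), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    params: dict[str, Tensor] = {
        "kp_W": lin(2 * N_JOINTS, d), "kp_b": zeros(d),
        "conv_W": Tensor(rng.uniform(-1, 1, (c, 1, k, k)) * np.sqrt(6.0 / (k * k + c * k * k)),
                         requires_grad=True),
        "conv_b": zeros(c),
        "patch_W": lin(patch_dim, d), "patch_b": zeros(d),
        "care_W": lin(1, d), "care_b": zeros(d),
        "learned_query": Tensor(rng.normal(0.0, 0.02, (1, d)), requires_grad=True),
        "cam_Wq": lin(d, d), "cam_bq": zeros(d),
        "cam_Wk": lin(d, d), "cam_bk": zeros(d),
        "cam_Wv": lin(d, d), "cam_bv": zeros(d),
        "cam_Wo": lin(d, d), "cam_bo": zeros(d),
        "cam_ffn1_W": lin(d, h), "cam_ffn1_b": zeros(h),
        "cam_ffn2_W": lin(h, d), "cam_ffn2_b": zeros(d),
    }
    for layer in range(config.n_temporal_layers):
        p = f"t{layer}_"
        params.update({
            p + "Wq": lin(d, d), p + "bq": zeros(d),
            p + "Wk": lin(d, d), p + "bk": zeros(d),
            p + "Wv": lin(d, d), p + "bv": zeros(d),
            p + "Wo": lin(d, d), p + "bo": zeros(d),
            p + "ffn1_W": lin(d, h), p + "ffn1_b": zeros(h),
            p + "ffn2_W": lin(h, d), p + "ffn2_b": zeros(d),
        })
    params["cls_W"] = lin(d, config.n_classes)
    params["cls_b"] = zeros(config.n_classes)
    return params


def parameter_count(params: dict[str, Tensor]) -> int:
    return int(sum(p.data.size for p in params.values()))


# ---------------------------------------------------------------------------
# Embeddings

def normalize_keypoints(kp_px: np.ndarray, frame_size: float = 640.0) -> np.ndarray:
    """Scale pixel coordinates into [0, 1] and center each frame on the hip
    midpoint, giving translation invariance across seating positions."""
    kp = np.asarray(kp_px)
    if not np.issubdtype(kp.dtype, np.floating):
        kp = kp.astype(np.float64)
    kp = kp / frame_size
    hip_mid = 0.5 * (kp[..., 11, :] + kp[..., 12, :])  # left_hip, right_hip
    return kp - hip_mid[..., None, :]


def embed_keypoints(frame_keypoints, params: dict[str, Tensor]) -> Tensor:
    """Linear projection of the flattened (x, y) key points (34 -> d)."""
    x = frame_keypoints.data if isinstance(frame_keypoints, Tensor) else np.asarray(frame_keypoints)
    if not np.all(np.isfinite(x)):
        raise ValueError("keypoints contain non-finite coordinates")
    flat = Tensor(x.reshape(x.shape[:-2] + (2 * N_JOINTS,)))
    return flat @ params["kp_W"] + params["kp_b"]


def embed_heatmap(maps, params: dict[str, Tensor], config: CSTTConfig) -> Tensor:
    """Convolve the heatmap(s), cut into non-overlapping patches, and project
    each flattened patch to a d-dimensional token.

    Accepts (64, 64), (B, 64, 64) or (B, T, 64, 64); token output has an
    extra leading patch axis of length ``config.n_patches``.
    """
    x = maps.data if isinstance(maps, Tensor) else np.asarray(maps)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    lead = x.shape[:-2]
    if x.shape[-2:] != (HEATMAP_SIZE, HEATMAP_SIZE):
        raise ValueError(f"heatmaps must be (..., 64, 64), got {x.shape}")
    n = int(np.prod(lead)) if lead else 1
    t = Tensor(x.reshape(n, 1, HEATMAP_SIZE, HEATMAP_SIZE))
    feat = conv2d(t, params["conv_W"], params["conv_b"])  # (n, C, 64, 64)
    g = HEATMAP_SIZE // config.heatmap_patch
    p = config.heatmap_patch
    c = config.conv_channels
    feat = feat.reshape(n, c, g, p, g, p)
    feat = feat.transpose(0, 2, 4, 1, 3, 5).reshape(n, g * g, c * p * p)
    tokens = feat @ params["patch_W"] + params["patch_b"]  # (n, T_p, d)
    return tokens.reshape(lead + (config.n_patches, params["patch_W"].shape[1]))


def embed_care_level(care_level, params: dict[str, Tensor]) -> Tensor:
    """Project the scalar care level, rescaled to ``(cl - 3)/2 in [-1, 1]``."""
    cl = np.asarray(care_level, dtype=np.float64)
    if np.any(cl < 1) or np.any(cl > 5):
        raise ValueError("care level must lie in 1..5")
    scaled = Tensor(((cl - 3.0) / 2.0).reshape(cl.shape + (1,))
                    .astype(params["care_W"].data.dtype))
    return scaled @ params["care_W"] + params["care_b"]


# ---------------------------------------------------------------------------
# Attention

def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, np.ndarray]:
    """``softmax(QK^T / sqrt(d_head)) V`` over the last two axes.

    Returns the attended values and the (detached) attention-weight array;
    every weight row sums to 1.
    """
    d_head = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (d_head ** -0.5)
    weights = scores.softmax(axis=-1)
    return weights @ v, weights.data.copy()


def care_aware_attention(tokens: FrameTokens, params: dict[str, Tensor]
                         ) -> tuple[Tensor, np.ndarray]:
    """Single-head CAM: the care query attends over the keypoint/heatmap
    tokens; the output is one d-vector per frame."""
    q = tokens.query @ params["cam_Wq"] + params["cam_bq"]
    k = tokens.keyvalue @ params["cam_Wk"] + params["cam_bk"]
    v = tokens.keyvalue @ params["cam_Wv"] + params["cam_bv"]
    return scaled_dot_attention(q, k, v)


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    """(..., n, d) -> (..., h, n, d/h)"""
    *lead, n, d = x.shape
    x = x.reshape(*lead, n, n_heads, d // n_heads)
    axes = tuple(range(len(lead))) + (x.ndim - 2, x.ndim - 3, x.ndim - 1)
    return x.transpose(*axes)


def _merge_heads(x: Tensor) -> Tensor:
    """(..., h, n, d/h) -> (..., n, d)"""
    *lead, h, n, dh = x.shape
    axes = tuple(range(len(lead))) + (x.ndim - 2, x.ndim - 3, x.ndim - 1)
    return x.transpose(*axes).reshape(*lead, n, h * dh)


def multihead_care_attention(tokens: FrameTokens, params: dict[str, Tensor],
                             n_heads: int) -> tuple[Tensor, np.ndarray]:
    """Multi-head CAM: per-head attention on d/h-dimensional projections,
    concatenated and projected by ``W_o``.

    Returns the (..., 1, d) attended feature and the weight array with a
    head axis, shape (..., h, 1, n_tokens).
    """
    q = tokens.query @ params["cam_Wq"] + params["cam_bq"]
    k = tokens.keyvalue @ params["cam_Wk"] + params["cam_bk"]
    v = tokens.keyvalue @ params["cam_Wv"] + params["cam_bv"]
    out, w = scaled_dot_attention(_split_heads(q, n_heads), _split_heads(k, n_heads),
                                  _split_heads(v, n_heads))
    return _merge_heads(out) @ params["cam_Wo"] + params["cam_bo"], w


def feedforward(x: Tensor, params: dict[str, Tensor], prefix: str = "cam_",
                dropout_mask: np.ndarray | None = None) -> Tensor:
    """Residual two-layer ReLU MLP on a layer-normalized input:
    ``x + W2 relu(W1 LN(x))`` (pre-norm placement)."""
    h = x.layer_norm() @ params[prefix + "ffn1_W"] + params[prefix + "ffn1_b"]
    h = h.relu()
    out = h @ params[prefix + "ffn2_W"] + params[prefix + "ffn2_b"]
    if dropout_mask is not None:
        out = out * Tensor(dropout_mask)
    return x + out


# ---------------------------------------------------------------------------
# Temporal encoder

def positional_encoding(t: int, d: int, rho: float = 10_000.0) -> np.ndarray:
    """Sinusoidal positional encoding: even dimensions sine, odd cosine,
    with frequency ``rho**(-2i/d)``."""
    if t < 1 or d < 1:
        raise ValueError("t and d must be >= 1")
    pos = np.arange(t)[:, None]
    i = np.arange(0, d, 2)[None, :]
    angle = pos / rho ** (i / d)
    pe = np.zeros((t, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : pe[:, 1::2].shape[1]])
    return pe


def _self_attention(x: Tensor, params: dict[str, Tensor], prefix: str,
                    n_heads: int) -> tuple[Tensor, np.ndarray]:
    q = x @ params[prefix + "Wq"] + params[prefix + "bq"]
    k = x @ params[prefix + "Wk"] + params[prefix + "bk"]
    v = x @ params[prefix + "Wv"] + params[prefix + "bv"]
    out, w = scaled_dot_attention(_split_heads(q, n_heads), _split_heads(k, n_heads),
                                  _split_heads(v, n_heads))
    return _merge_heads(out) @ params[prefix + "Wo"] + params[prefix + "bo"], w


def temporal_encode(z: Tensor, params: dict[str, Tensor], config: CSTTConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Tensor, list[np.ndarray]]:
    """Pre-norm transformer encoder over the frame axis.

    Each layer applies multi-head self-attention and a residual FFN, both on
    layer-normalized inputs.  Zero layers is the identity.  Returns the
    encoded sequence and the per-layer attention weights.
    """
    attn_maps: list[np.ndarray] = []
    x = z
    for layer in range(config.n_temporal_layers):
        prefix = f"t{layer}_"
        attn, w = _self_attention(x.layer_norm(), params, prefix, config.n_heads)
        attn_maps.append(w)
        if rng is not None and config.dropout > 0:
            attn = attn * Tensor(_dropout_mask(rng, attn.shape, config.dropout,
                                               attn.data.dtype))
        x = x + attn
        mask = (_dropout_mask(rng, (x.shape[:-1] + (config.latent_dim,)),
                              config.dropout, x.data.dtype)
                if rng is not None and config.dropout > 0 else None)
        x = feedforward(x, params, prefix=prefix, dropout_mask=mask)
    return x, attn_maps


def mean_pool(z: Tensor) -> Tensor:
    """Arithmetic mean over the temporal axis: (..., T, d) -> (..., d)."""
    if z.shape[-2] < 1:
        raise ValueError("cannot pool an empty sequence")
    return z.mean(axis=-2)


def classify(z: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Softmax classifier over activity categories; rows sum to 1."""
    logits = z @ params["cls_W"] + params["cls_b"]
    return logits.softmax(axis=-1)


def _dropout_mask(rng: np.random.Generator, shape, rate: float,
                  dtype=np.float64) -> np.ndarray:
    keep = rng.random(shape) >= rate
    return (keep / (1.0 - rate)).astype(dtype)


# ---------------------------------------------------------------------------
# Full forward pass

def _joint_mask(seed: int, rate: float) -> np.ndarray:
    """Deterministic per-sample partial-skeleton mask: ``rate`` of the 17
    joints are zeroed, the subset fixed by the seed."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0x3A5])))
    n_drop = int(round(rate * N_JOINTS))
    mask = np.ones(N_JOINTS)
    mask[rng.choice(N_JOINTS, size=n_drop, replace=False)] = 0.0
    return mask


def forward_batch(
    params: dict[str, Tensor],
    config: CSTTConfig,
    kp_px: np.ndarray,  # (B, T, 17, 2) raw pixels
    heatmaps: np.ndarray,  # (B, T, 64, 64)
    care_levels: np.ndarray,  # (B,)
    mode: ModelMode | str = "cstt",
    rng: np.random.Generator | None = None,
    mask_seeds: np.ndarray | None = None,
) -> tuple[Tensor, dict]:
    """Run the full pipeline on a batch of windows.

    Returns the (B, n_classes) probability tensor and a diagnostics dict with
    the CAM attention weights (B, T, heads, n_tokens), the token-group
    labels, and the temporal attention maps.  ``rng`` enables dropout
    (training); without it the pass is deterministic.
    """
    mode = MODES[mode] if isinstance(mode, str) else mode
    dtype = params["kp_W"].data.dtype
    kp_px = np.asarray(kp_px, dtype=dtype)
    heatmaps = np.asarray(heatmaps, dtype=dtype)
    care_levels = np.asarray(care_levels)
    b, t = kp_px.shape[0], kp_px.shape[1]
    if t != config.window:
        raise ValueError(f"window length {t} does not match config.window={config.window}")

    token_groups: list[str] = []
    kv_parts: list[Tensor] = []
    if mode.use_skeleton:
        kp = normalize_keypoints(kp_px, config.frame_size)
        if mode.partial_skeleton:
            seeds = (mask_seeds if mask_seeds is not None else np.arange(b))
            masks = np.stack([_joint_mask(int(s), config.partial_mask_rate)
                              for s in seeds]).astype(dtype)  # (B, 17)
            kp = kp * masks[:, None, :, None]
        k_tok = embed_keypoints(kp, params)  # (B, T, d)
        kv_parts.append(k_tok.reshape(b, t, 1, config.latent_dim))
        token_groups.append("keypoints")
    if mode.use_heatmap:
        h_tok = embed_heatmap(heatmaps, params, config)  # (B, T, T_p, d)
        kv_parts.append(h_tok)
        token_groups.extend(["heatmap"] * config.n_patches)

    care_emb = None
    if mode.care_query or mode.care_token:
        care_emb = embed_care_level(care_levels, params)  # (B, d)
    if mode.care_token:
        care_kv = care_emb.reshape(b, 1, 1, config.latent_dim)
        tiled = care_kv + Tensor(np.zeros((b, t, 1, config.latent_dim), dtype=dtype))
        kv_parts.append(tiled)
        token_groups.append("care")
    keyvalue = kv_parts[0] if len(kv_parts) == 1 else concat(kv_parts, axis=2)

    # the query broadcasts over the frame axis inside the attention matmuls
    if mode.care_query:
        query = care_emb.reshape(b, 1, 1, config.latent_dim)
    else:
        query = params["learned_query"].reshape(1, 1, 1, config.latent_dim)

    frame_feat, cam_w = multihead_care_attention(
        FrameTokens(query=query, keyvalue=keyvalue), params, config.n_heads
    )  # (B, T, 1, d), weights (B, T, h, 1, n_tok)
    frame_feat = frame_feat.reshape(b, t, config.latent_dim)
    if rng is not None and config.dropout > 0:
        frame_feat = frame_feat * Tensor(
            _dropout_mask(rng, frame_feat.shape, config.dropout, dtype)
        )
    mask = (_dropout_mask(rng, frame_feat.shape, config.dropout, dtype)
            if rng is not None and config.dropout > 0 else None)
    frame_feat = feedforward(frame_feat, params, prefix="cam_", dropout_mask=mask)

    pe = Tensor(positional_encoding(t, config.latent_dim, config.pe_constant)
                .astype(dtype))
    z, temporal_w = temporal_encode(frame_feat + pe, params, config, rng=rng)
    probs = classify(mean_pool(z), params)
    diagnostics = {
        "cam_attention": cam_w[:, :, :, 0, :],  # (B, T, h, n_tok)
        "token_groups": token_groups,
        "temporal_attention": temporal_w,
        "mode": mode.name,
    }
    return probs, diagnostics


def forward(sample: LabeledSample, params: dict[str, Tensor], config: CSTTConfig,
            mode: ModelMode | str = "cstt", mask_seed: int = 0) -> tuple[np.ndarray, dict]:
    """Classify a single window sample; returns (probabilities, diagnostics)."""
    if sample.frames != config.window:
        raise ValueError("sample must be a window of config.window frames")
    probs, diag = forward_batch(
        params, config,
        sample.skeleton.keypoints[None],
        sample.heatmaps.maps[None],
        np.asarray([sample.care.care_level]),
        mode=mode,
        mask_seeds=np.asarray([mask_seed]),
    )
    return probs.data[0], diag


# ---------------------------------------------------------------------------
# Checkpoints

def save_checkpoint(path, params: dict[str, Tensor], config: CSTTConfig) -> None:
    """Single-file archive: config as a YAML block plus named weight arrays."""
    payload = {f"param/{k}": v.data for k, v in params.items()}
    payload["schema"] = np.array(CHECKPOINT_SCHEMA)
    payload["config_yaml"] = np.array(yaml.safe_dump(dataclasses.asdict(config)))
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> tuple[dict[str, Tensor], CSTTConfig]:
    with np.load(path, allow_pickle=False) as archive:
        schema = str(archive["schema"])
        if schema != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {schema!r}")
        config = CSTTConfig(**yaml.safe_load(io.StringIO(str(archive["config_yaml"]))))
        params = {
            k[len("param/"):]: Tensor(archive[k], requires_grad=True)
            for k in archive.files if k.startswith("param/")
        }
    return params, config
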