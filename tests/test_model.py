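"""CSTT network components against independent hand-rolled oracles."""

import numpy as np
import pytest

from cstt.autograd import Tensor
from cstt.model import (
    CSTTConfig,
    FrameTokens,
    MODES,
    care_aware_attention,
    classify,
    embed_care_level,
    embed_heatmap,
    embed_keypoints,
    feedforward,
    forward_batch,
    init_params,
    load_checkpoint,
    mean_pool,
    multihead_care_attention,
    normalize_keypoints,
    parameter_count,
    positional_encoding,
    save_checkpoint,
    scaled_dot_attention,
    temporal_encode,
)
from cstt.training import _cross_entropy


def small_config(**kw):
    defaults = dict(latent_dim=8, n_heads=2, n_temporal_layers=1, ffn_hidden=16,
                    window=2, heatmap_patch=32, conv_channels=1, dropout=0.0)
    defaults.update(kw)
    return CSTTConfig(**defaults)


# -- embeddings --------------------------------------------------------------

def test_keypoint_embedding_matches_matmul_oracle(rng):
    cfg = small_config()
    params = init_params(cfg, seed=0)
    kp = rng.normal(size=(17, 2))
    out = embed_keypoints(kp, params).data
    expected = kp.reshape(34) @ params["kp_W"].data + params["kp_b"].data
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_keypoint_embedding_linear_and_zero(rng):
    params = init_params(small_config(), seed=0)
    kp = rng.normal(size=(17, 2))
    f = lambda x: embed_keypoints(x, params).data
    np.testing.assert_allclose(f(3.0 * kp), 3.0 * f(kp), atol=1e-10)
    np.testing.assert_allclose(f(np.zeros((17, 2))), np.zeros(8), atol=0)


def test_keypoint_embedding_rejects_nan(rng):
    params = init_params(small_config(), seed=0)
    kp = np.full((17, 2), np.nan)
    with pytest.raises(ValueError):
        embed_keypoints(kp, params)


def test_normalize_keypoints_centers_hip_midpoint(rng):
    kp = rng.uniform(0, 640, (5, 17, 2))
    norm = normalize_keypoints(kp, 640.0)
    hip_mid = 0.5 * (norm[:, 11] + norm[:, 12])
    np.testing.assert_allclose(hip_mid, 0.0, atol=1e-12)
    shifted = normalize_keypoints(kp + 100.0, 640.0)
    np.testing.assert_allclose(shifted, norm, atol=1e-12)  # translation invariant


def test_heatmap_embedding_matches_explicit_conv_oracle(rng):
    cfg = small_config()
    params = init_params(cfg, seed=1)
    img = rng.random((64, 64))
    tokens = embed_heatmap(img, params, cfg).data  # (4, 8)
    w = params["conv_W"].data[0, 0]  # single in/out channel, 3x3
    conv = np.zeros((64, 64))
    pad = np.pad(img, 1)
    for y in range(64):
        for x in range(64):
            conv[y, x] = (pad[y:y + 3, x:x + 3] * w).sum()
    conv += params["conv_b"].data[0]
    expected = np.zeros((4, 8))
    for gy in range(2):
        for gx in range(2):
            patch = conv[gy * 32:(gy + 1) * 32, gx * 32:(gx + 1) * 32].reshape(-1)
            expected[gy * 2 + gx] = patch @ params["patch_W"].data + params["patch_b"].data
    np.testing.assert_allclose(tokens, expected, atol=1e-9)


def test_heatmap_embedding_zero_map_zero_bias_gives_zero_tokens(rng):
    cfg = small_config()
    params = init_params(cfg, seed=1)
    params["conv_b"].data[:] = 0.0
    params["patch_b"].data[:] = 0.0
    tokens = embed_heatmap(np.zeros((64, 64)), params, cfg).data
    np.testing.assert_allclose(tokens, 0.0, atol=0)


def test_heatmap_embedding_degenerate_single_patch(rng):
    """patch = 64: one token equal to the (identity-convolved) flattened map
    times the projection."""
    cfg = small_config(heatmap_patch=64)
    params = init_params(cfg, seed=2)
    params["conv_W"].data[:] = 0.0
    params["conv_W"].data[0, 0, 1, 1] = 1.0  # identity kernel
    params["conv_b"].data[:] = 0.0
    img = rng.random((64, 64))
    tokens = embed_heatmap(img, params, cfg).data
    assert tokens.shape == (1, 8)
    expected = img.reshape(-1) @ params["patch_W"].data + params["patch_b"].data
    np.testing.assert_allclose(tokens[0], expected, atol=1e-10)


def test_care_embedding_scaling_and_oracle(rng):
    cfg = small_config()
    params = init_params(cfg, seed=3)
    params["care_b"].data[:] = 0.0
    np.testing.assert_allclose(embed_care_level(3, params).data, 0.0, atol=0)
    out5 = embed_care_level(5, params).data
    np.testing.assert_allclose(out5, 1.0 * params["care_W"].data[0], atol=1e-12)
    params["care_W"].data[:] = 0.0
    params["care_W"].data[0, 0] = 1.0
    np.testing.assert_allclose(embed_care_level(5, params).data,
                               np.eye(8)[0], atol=1e-12)
    with pytest.raises(ValueError):
        embed_care_level(6, params)


# -- attention ---------------------------------------------------------------

def test_attention_singleton_key_returns_value(rng):
    q = Tensor(rng.normal(size=(1, 4)))
    k = Tensor(rng.normal(size=(1, 4)))
    v = Tensor(rng.normal(size=(1, 4)))
    out, w = scaled_dot_attention(q, k, v)
    np.testing.assert_allclose(out.data, v.data, atol=1e-12)
    np.testing.assert_allclose(w, [[1.0]], atol=0)


def test_attention_identical_keys_give_uniform_weights(rng):
    q = Tensor(rng.normal(size=(1, 4)))
    k = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)))
    v = Tensor(rng.normal(size=(5, 4)))
    _, w = scaled_dot_attention(q, k, v)
    np.testing.assert_allclose(w, 0.2, atol=1e-12)


def test_attention_matches_exp_normalize_oracle(rng):
    for _ in range(50):
        q = rng.normal(size=(2, 4))
        k = rng.normal(size=(3, 4))
        v = rng.normal(size=(3, 4))
        out, w = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v))
        scores = q @ k.T / np.sqrt(4)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        expected_w = e / e.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(w, expected_w, atol=1e-10)
        np.testing.assert_allclose(out.data, expected_w @ v, atol=1e-10)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)


def test_single_head_cam_keypoint_token_only(rng):
    """With no heatmap patches the single key/value token is returned
    (projected), with weight exactly 1."""
    cfg = small_config()
    params = init_params(cfg, seed=4)
    tokens = FrameTokens(query=Tensor(rng.normal(size=(1, 8))),
                         keyvalue=Tensor(rng.normal(size=(1, 8))))
    out, w = care_aware_attention(tokens, params)
    expected = (tokens.keyvalue.data @ params["cam_Wv"].data
                + params["cam_bv"].data)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)
    np.testing.assert_allclose(w, [[1.0]], atol=0)


def test_care_level_steers_attention(rng):
    cfg = small_config()
    params = init_params(cfg, seed=5)
    kv = Tensor(rng.normal(size=(6, 8)))
    diffs = []
    for _ in range(10):
        c1 = embed_care_level(1, params).reshape(1, 8)
        c5 = embed_care_level(5, params).reshape(1, 8)
        _, w1 = care_aware_attention(FrameTokens(c1, kv), params)
        _, w5 = care_aware_attention(FrameTokens(c5, kv), params)
        diffs.append(np.abs(w1 - w5).max())
    assert max(diffs) > 1e-4


def test_multihead_single_head_identity_wo_equals_single(rng):
    cfg = small_config(n_heads=1)
    params = init_params(cfg, seed=6)
    params["cam_Wo"].data = np.eye(8)
    params["cam_bo"].data[:] = 0.0
    tokens = FrameTokens(Tensor(rng.normal(size=(1, 8))),
                         Tensor(rng.normal(size=(5, 8))))
    single, _ = care_aware_attention(tokens, params)
    multi, _ = multihead_care_attention(tokens, params, n_heads=1)
    np.testing.assert_allclose(multi.data, single.data, atol=1e-12)


def test_multihead_matches_two_slice_oracle(rng):
    cfg = small_config()
    params = init_params(cfg, seed=7)
    q = rng.normal(size=(1, 8))
    kv = rng.normal(size=(5, 8))
    out, w = multihead_care_attention(FrameTokens(Tensor(q), Tensor(kv)),
                                      params, n_heads=2)
    qp = q @ params["cam_Wq"].data + params["cam_bq"].data
    kp = kv @ params["cam_Wk"].data + params["cam_bk"].data
    vp = kv @ params["cam_Wv"].data + params["cam_bv"].data
    heads = []
    for h in range(2):
        sl = slice(4 * h, 4 * (h + 1))
        scores = qp[:, sl] @ kp[:, sl].T / 2.0  # sqrt(d_head)=2
        e = np.exp(scores - scores.max())
        weights = e / e.sum()
        np.testing.assert_allclose(w[h], weights, atol=1e-10)
        heads.append(weights @ vp[:, sl])
    expected = np.concatenate(heads, axis=-1) @ params["cam_Wo"].data \
        + params["cam_bo"].data
    np.testing.assert_allclose(out.data, expected, atol=1e-10)


def test_attention_is_permutation_equivariant_over_tokens(rng):
    params = init_params(small_config(), seed=8)
    q = Tensor(rng.normal(size=(1, 8)))
    kv = rng.normal(size=(6, 8))
    perm = np.random.default_rng(0).permutation(6)
    out1, _ = multihead_care_attention(FrameTokens(q, Tensor(kv)), params, 2)
    out2, _ = multihead_care_attention(FrameTokens(q, Tensor(kv[perm])), params, 2)
    np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)


# -- feedforward, encoding, pooling, classifier ------------------------------

def test_feedforward_zero_weights_is_identity(rng):
    params = init_params(small_config(), seed=9)
    for k in ("cam_ffn1_W", "cam_ffn1_b", "cam_ffn2_W", "cam_ffn2_b"):
        params[k].data[:] = 0.0
    x = Tensor(rng.normal(size=(3, 8)))
    np.testing.assert_allclose(feedforward(x, params).data, x.data, atol=0)


def test_feedforward_matches_two_matmul_oracle(rng):
    params = init_params(small_config(), seed=10)
    x = rng.normal(size=(3, 8))
    out = feedforward(Tensor(x), params).data
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    ln = (x - mu) / np.sqrt(var + 1e-5)
    h = np.maximum(ln @ params["cam_ffn1_W"].data + params["cam_ffn1_b"].data, 0)
    expected = x + h @ params["cam_ffn2_W"].data + params["cam_ffn2_b"].data
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_positional_encoding_properties(rng):
    pe = positional_encoding(7, 10, 10_000.0)
    np.testing.assert_allclose(pe[0, 0::2], 0.0, atol=0)
    np.testing.assert_allclose(pe[0, 1::2], 1.0, atol=0)
    assert np.abs(pe).max() <= 1.0
    t, d = int(rng.integers(1, 20)), 2 * int(rng.integers(1, 10))
    pe = positional_encoding(t, d)
    for pos in range(t):
        for i in range(d // 2):
            angle = pos / 10_000.0 ** (2 * i / d)
            assert pe[pos, 2 * i] == pytest.approx(np.sin(angle), abs=1e-12)
            assert pe[pos, 2 * i + 1] == pytest.approx(np.cos(angle), abs=1e-12)


def test_temporal_encoder_zero_layers_is_identity(rng):
    cfg = small_config(n_temporal_layers=0)
    params = init_params(cfg, seed=11)
    z = Tensor(rng.normal(size=(2, 5, 8)))
    out, maps = temporal_encode(z, params, cfg)
    np.testing.assert_allclose(out.data, z.data, atol=0)
    assert maps == []


def test_temporal_encoder_matches_from_scratch_oracle(rng):
    cfg = small_config(latent_dim=4, n_heads=1, ffn_hidden=6)
    params = init_params(cfg, seed=12)
    z = rng.normal(size=(2, 4))  # T=2, d=4

    def ln(x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + 1e-5)

    p = {k: v.data for k, v in params.items()}
    h = ln(z)
    q = h @ p["t0_Wq"] + p["t0_bq"]
    k = h @ p["t0_Wk"] + p["t0_bk"]
    v = h @ p["t0_Wv"] + p["t0_bv"]
    scores = q @ k.T / 2.0
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    w = e / e.sum(axis=-1, keepdims=True)
    x = z + (w @ v) @ p["t0_Wo"] + p["t0_bo"]
    h2 = np.maximum(ln(x) @ p["t0_ffn1_W"] + p["t0_ffn1_b"], 0)
    expected = x + h2 @ p["t0_ffn2_W"] + p["t0_ffn2_b"]

    out, maps = temporal_encode(Tensor(z[None]), params, cfg)
    np.testing.assert_allclose(out.data[0], expected, atol=1e-8)
    np.testing.assert_allclose(maps[0][0, 0], w, atol=1e-10)


def test_mean_pool(rng):
    x = rng.normal(size=(4, 6))
    np.testing.assert_allclose(mean_pool(Tensor(x)).data, x.mean(axis=0),
                               atol=1e-12)
    v = rng.normal(size=6)
    np.testing.assert_allclose(mean_pool(Tensor(np.stack([v, -v]))).data,
                               0.0, atol=1e-12)


def test_classifier_uniform_saturation_and_oracle(rng):
    cfg = small_config()
    params = init_params(cfg, seed=13)
    params["cls_W"].data[:] = 0.0
    params["cls_b"].data[:] = 0.0
    probs = classify(Tensor(rng.normal(size=8)), params).data
    np.testing.assert_allclose(probs, 0.25, atol=1e-12)
    params["cls_b"].data[:] = [1000.0, 0, 0, 0]
    probs = classify(Tensor(np.zeros(8)), params).data
    assert probs[0] == pytest.approx(1.0)
    for _ in range(50):
        params["cls_W"].data = rng.normal(size=(8, 4))
        params["cls_b"].data = rng.normal(size=4)
        z = rng.normal(size=8)
        probs = classify(Tensor(z), params).data
        logits = z @ params["cls_W"].data + params["cls_b"].data
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(probs, e / e.sum(), atol=1e-10)
        assert probs.sum() == pytest.approx(1.0)


# -- full forward ------------------------------------------------------------

def _toy_batch(rng, cfg, b=3):
    kp = rng.uniform(100, 500, (b, cfg.window, 17, 2))
    hm = rng.random((b, cfg.window, 64, 64))
    care = np.array([1, 3, 5][:b])
    return kp, hm, care


def _ref_forward(p, cfg, kp, hm, cl, mode="cstt"):
    """Plain-NumPy single-sample reference of the whole pipeline."""
    d, heads = cfg.latent_dim, cfg.n_heads
    dh = d // heads

    def ln(x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + 1e-5)

    def mha(q, kv, prefix):
        qp = q @ p[prefix + "Wq"] + p[prefix + "bq"]
        kp_ = kv @ p[prefix + "Wk"] + p[prefix + "bk"]
        vp = kv @ p[prefix + "Wv"] + p[prefix + "bv"]
        outs = []
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            scores = qp[:, sl] @ kp_[:, sl].T / np.sqrt(dh)
            e = np.exp(scores - scores.max(axis=-1, keepdims=True))
            outs.append((e / e.sum(axis=-1, keepdims=True)) @ vp[:, sl])
        return np.concatenate(outs, axis=-1) @ p[prefix + "Wo"] + p[prefix + "bo"]

    norm = kp / cfg.frame_size
    norm = norm - 0.5 * (norm[:, 11] + norm[:, 12])[:, None, :]
    frame_feats = []
    g = 64 // cfg.heatmap_patch
    for t in range(cfg.window):
        k_tok = norm[t].reshape(34) @ p["kp_W"] + p["kp_b"]
        pad = np.pad(hm[t], 1)
        conv = np.zeros((cfg.conv_channels, 64, 64))
        for c in range(cfg.conv_channels):
            for y in range(64):
                for x in range(64):
                    conv[c, y, x] = (pad[y:y + 3, x:x + 3] * p["conv_W"][c, 0]).sum()
            conv[c] += p["conv_b"][c]
        h_toks = []
        for gy in range(g):
            for gx in range(g):
                patch = conv[:, gy * cfg.heatmap_patch:(gy + 1) * cfg.heatmap_patch,
                             gx * cfg.heatmap_patch:(gx + 1) * cfg.heatmap_patch]
                h_toks.append(patch.reshape(-1) @ p["patch_W"] + p["patch_b"])
        kv = np.vstack([k_tok[None], np.stack(h_toks)])
        if mode == "cstt":
            q = ((cl - 3.0) / 2.0) * p["care_W"][0] + p["care_b"]
        else:
            q = p["learned_query"][0]
        attn = mha(q[None], kv, "cam_")
        hmid = np.maximum(ln(attn) @ p["cam_ffn1_W"] + p["cam_ffn1_b"], 0)
        frame_feats.append((attn + hmid @ p["cam_ffn2_W"] + p["cam_ffn2_b"])[0])
    z = np.stack(frame_feats) + positional_encoding(cfg.window, d, cfg.pe_constant)
    for layer in range(cfg.n_temporal_layers):
        pre = f"t{layer}_"
        h = ln(z)
        z = z + mha(h, h, pre)
        h2 = np.maximum(ln(z) @ p[pre + "ffn1_W"] + p[pre + "ffn1_b"], 0)
        z = z + h2 @ p[pre + "ffn2_W"] + p[pre + "ffn2_b"]
    pooled = z.mean(axis=0)
    logits = pooled @ p["cls_W"] + p["cls_b"]
    e = np.exp(logits - logits.max())
    return e / e.sum()


def test_forward_matches_from_scratch_reference(rng):
    cfg = small_config()
    params = init_params(cfg, seed=20)
    kp, hm, care = _toy_batch(rng, cfg)
    p = {k: v.data for k, v in params.items()}
    for mode in ("cstt", "tstt"):
        probs, _ = forward_batch(params, cfg, kp, hm, care, mode=mode)
        for i in range(3):
            expected = _ref_forward(p, cfg, kp[i], hm[i], care[i], mode)
            np.testing.assert_allclose(probs.data[i], expected, atol=1e-6)


@pytest.mark.parametrize("mode", sorted(MODES))
def test_probabilities_sum_to_one_in_every_mode(mode, rng):
    cfg = small_config()
    params = init_params(cfg, seed=21)
    kp, hm, care = _toy_batch(rng, cfg)
    probs, diag = forward_batch(params, cfg, kp, hm, care, mode=mode)
    np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-9)
    w = diag["cam_attention"]
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-9)
    n_tok = len(diag["token_groups"])
    assert w.shape[-1] == n_tok


def test_tstt_output_invariant_to_care_level(rng):
    cfg = small_config()
    params = init_params(cfg, seed=22)
    kp, hm, _ = _toy_batch(rng, cfg)
    p1, _ = forward_batch(params, cfg, kp, hm, np.array([1, 1, 1]), mode="tstt")
    p5, _ = forward_batch(params, cfg, kp, hm, np.array([5, 5, 5]), mode="tstt")
    np.testing.assert_array_equal(p1.data, p5.data)


def test_cstt_output_sensitive_to_care_level(rng):
    cfg = small_config()
    params = init_params(cfg, seed=23)
    kp, hm, _ = _toy_batch(rng, cfg)
    p1, _ = forward_batch(params, cfg, kp, hm, np.array([1, 1, 1]), mode="cstt")
    p5, _ = forward_batch(params, cfg, kp, hm, np.array([5, 5, 5]), mode="cstt")
    assert np.abs(p1.data - p5.data).max() > 1e-8


def test_care_gradient_nonzero_in_cstt_zero_in_tstt(rng):
    cfg = small_config()
    kp, hm, care = _toy_batch(rng, cfg)
    labels = np.array([0, 1, 2])
    grads = {}
    for mode in ("cstt", "tstt"):
        params = init_params(cfg, seed=24)
        probs, _ = forward_batch(params, cfg, kp, hm, care, mode=mode)
        _cross_entropy(probs, labels).backward()
        grads[mode] = params["care_W"].grad
    assert grads["cstt"] is not None and np.abs(grads["cstt"]).max() > 0
    assert grads["tstt"] is None  # care embedding never enters the graph


def test_partial_skeleton_masks_fixed_fraction_of_joints(rng):
    from cstt.model import _joint_mask

    m1 = _joint_mask(7, 0.3)
    m2 = _joint_mask(7, 0.3)
    np.testing.assert_array_equal(m1, m2)
    assert (m1 == 0).sum() == round(0.3 * 17)
    cfg = small_config()
    params = init_params(cfg, seed=25)
    kp, hm, care = _toy_batch(rng, cfg)
    full, _ = forward_batch(params, cfg, kp, hm, care, mode="cstt")
    part, _ = forward_batch(params, cfg, kp, hm, care, mode="sp+d+c",
                            mask_seeds=np.array([1, 2, 3]))
    assert np.abs(full.data - part.data).max() > 0


def test_wrong_window_length_rejected(rng):
    cfg = small_config()
    params = init_params(cfg, seed=26)
    with pytest.raises(ValueError, match="window"):
        forward_batch(params, cfg, rng.random((1, 5, 17, 2)),
                      rng.random((1, 5, 64, 64)), np.array([3]))


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = small_config()
    params = init_params(cfg, seed=27)
    path = tmp_path / "model.ckpt"
    save_checkpoint(path, params, cfg)
    params2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    assert parameter_count(params2) == parameter_count(params)
    kp, hm, care = _toy_batch(rng, cfg)
    p1, _ = forward_batch(params, cfg, kp, hm, care)
    p2, _ = forward_batch(params2, cfg2, kp, hm, care)
    np.testing.assert_array_equal(p1.data, p2.data)
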