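"""Attention fusion blocks against scalar loop-based reference evaluations."""

import numpy as np
import pytest

from semfuse import autograd as ag
from semfuse.attention import (CrossBranchAttention, CrossModalAttention,
                               CrossScaleAttention, FusionBlock, FusionModel,
                               ReconstructionHead, fuse_images)
from semfuse.autograd import Tensor


# ---------------------------------------------------------------- oracles
def loop_conv(x, w, b, stride=1, pad=None):
    """Scalar reference convolution, reflective padding, NCHW (single image)."""
    o, c, kh, kw = w.shape
    p = kh // 2 if pad is None else pad
    if p:
        xp = np.pad(x, ((0, 0), (p, p), (p, p)), mode="reflect")
    else:
        xp = x
    h = (xp.shape[1] - kh) // stride + 1
    wd = (xp.shape[2] - kw) // stride + 1
    out = np.zeros((o, h, wd))
    for oc in range(o):
        for y in range(h):
            for xx in range(wd):
                acc = 0.0 if b is None else b[oc]
                for ic in range(c):
                    for dy in range(kh):
                        for dx in range(kw):
                            acc += w[oc, ic, dy, dx] * \
                                xp[ic, y * stride + dy, xx * stride + dx]
                out[oc, y, xx] = acc
    return out


def loop_bn_eval(x, bn):
    gamma, beta = bn.gamma.data, bn.beta.data
    rm, rv = bn.running_mean, bn.running_var
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        out[c] = (x[c] - rm[c]) / np.sqrt(rv[c] + bn.eps) * gamma[c] + beta[c]
    return out


def sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def hswish(x):
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def _set_bn_stats(module, rng):
    """Give every BatchNorm nontrivial running statistics for eval mode."""
    from semfuse.nn import BatchNorm2d

    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            n = m.running_mean.shape[0]
            m._set_buffer("running_mean", rng.normal(0, 0.2, n))
            m._set_buffer("running_var", rng.uniform(0.5, 1.5, n))
            m.gamma.data = rng.uniform(0.8, 1.2, n)
            m.beta.data = rng.normal(0, 0.1, n)


# -------------------------------------------------------------- cross-modal
def cross_modal_oracle(mod, fa, fb):
    fa_n = loop_bn_eval(fa, mod.bn_a)
    fb_n = loop_bn_eval(fb, mod.bn_b)
    m_a = sig(loop_conv(np.maximum(loop_conv(fa_n, mod.a_conv1.weight.data,
                                             mod.a_conv1.bias.data), 0),
                        mod.a_conv2.weight.data, mod.a_conv2.bias.data))
    m_b = sig(loop_conv(np.maximum(loop_conv(fb_n, mod.b_conv1.weight.data,
                                             mod.b_conv1.bias.data), 0),
                        mod.b_conv2.weight.data, mod.b_conv2.bias.data))
    att_a = fa_n * (1.0 + m_a + m_b)
    att_b = fb_n * (1.0 + m_b + m_a)
    cat = np.concatenate([att_a, att_b], axis=0)
    return loop_conv(cat, mod.reduce.weight.data, mod.reduce.bias.data, pad=0)


def test_cross_modal_matches_loop_oracle(rng):
    mod = CrossModalAttention(1, rng=np.random.default_rng(8)).eval()
    _set_bn_stats(mod, rng)
    fa = rng.random((1, 4, 4))
    fb = rng.random((1, 4, 4))
    out = mod(Tensor(fa[None]), Tensor(fb[None])).numpy()[0]
    np.testing.assert_allclose(out, cross_modal_oracle(mod, fa, fb), atol=1e-5)


def test_cross_modal_zero_attention_weights_double_features(rng):
    mod = CrossModalAttention(2, rng=np.random.default_rng(8)).eval()
    for conv in (mod.a_conv1, mod.a_conv2, mod.b_conv1, mod.b_conv2):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    fa = Tensor(rng.random((1, 2, 4, 4)))
    fb = Tensor(rng.random((1, 2, 4, 4)))
    fa_n = mod.bn_a(fa)
    m_a, m_b = mod.masks(fa_n, mod.bn_b(fb))
    np.testing.assert_allclose(m_a.numpy(), 0.5)
    np.testing.assert_allclose(m_b.numpy(), 0.5)
    # each attended feature equals 2 * normalized feature
    att = fa_n * (1.0 + m_a + m_b)
    np.testing.assert_allclose(att.numpy(), 2.0 * fa_n.numpy())


def test_cross_modal_rejects_shape_mismatch(rng):
    mod = CrossModalAttention(1, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        mod(Tensor(rng.random((1, 1, 4, 4))), Tensor(rng.random((1, 1, 8, 8))))


# ------------------------------------------------------------- cross-branch
def cross_branch_oracle(mod, branches):
    f = np.concatenate(branches, axis=0)
    pooled_max = f.max(axis=(1, 2), keepdims=True)
    pooled_avg = f.mean(axis=(1, 2), keepdims=True)

    def mask(desc):
        h = np.maximum(loop_conv(desc, mod.squeeze.weight.data,
                                 mod.squeeze.bias.data, pad=0), 0)
        return sig(loop_conv(h, mod.excite.weight.data,
                             mod.excite.bias.data, pad=0))

    f_att = f * (1.0 + mask(pooled_max) + mask(pooled_avg))
    red = loop_conv(f_att, mod.reduce.weight.data, mod.reduce.bias.data, pad=0)
    return loop_bn_eval(red, mod.bn)


def test_cross_branch_matches_loop_oracle(rng):
    mod = CrossBranchAttention(2, rng=np.random.default_rng(9)).eval()
    _set_bn_stats(mod, rng)
    branches = [rng.random((2, 4, 4)) for _ in range(3)]
    out = mod([Tensor(b[None]) for b in branches]).numpy()[0]
    np.testing.assert_allclose(out, cross_branch_oracle(mod, branches),
                               atol=1e-5)


def test_cross_branch_constant_input_gives_equal_masks(rng):
    mod = CrossBranchAttention(2, rng=np.random.default_rng(9)).eval()
    f = Tensor(np.full((1, 6, 4, 4), 0.3))
    m_max, m_avg = mod.masks(f)
    np.testing.assert_allclose(m_max.numpy(), m_avg.numpy())


# -------------------------------------------------------------- cross-scale
def cross_scale_oracle(mod, cur, prev):
    f = np.concatenate([cur, prev], axis=0)
    row = f.mean(axis=2, keepdims=True)   # (C, H, 1)
    col = f.mean(axis=1, keepdims=True)   # (C, 1, W)

    def mask(desc, conv_dir):
        h = loop_conv(desc, mod.shared.weight.data, mod.shared.bias.data,
                      pad=0)
        h = hswish(loop_bn_eval(h, mod.shared_bn))
        return sig(loop_conv(h, conv_dir.weight.data, conv_dir.bias.data,
                             pad=0))

    m_x = mask(row, mod.conv_x)
    m_y = mask(col, mod.conv_y)
    f_att = f * (1.0 + m_x + m_y)
    red = loop_conv(f_att, mod.reduce.weight.data, mod.reduce.bias.data, pad=0)
    return loop_bn_eval(red, mod.bn)


def test_cross_scale_matches_loop_oracle(rng):
    mod = CrossScaleAttention(1, rng=np.random.default_rng(10)).eval()
    _set_bn_stats(mod, rng)
    cur = rng.random((1, 4, 4))
    prev = rng.random((1, 4, 4))
    out = mod(Tensor(cur[None]), Tensor(prev[None])).numpy()[0]
    np.testing.assert_allclose(out, cross_scale_oracle(mod, cur, prev),
                               atol=1e-5)


def test_cross_scale_transpose_symmetry(rng):
    """Transposing the input and swapping the x/y branches transposes the
    output (construction symmetry of coordinate attention)."""
    mod = CrossScaleAttention(1, rng=np.random.default_rng(11)).eval()
    cur = rng.random((1, 4, 4))
    prev = rng.random((1, 4, 4))
    out = mod(Tensor(cur[None]), Tensor(prev[None])).numpy()
    mod.conv_x, mod.conv_y = mod.conv_y, mod.conv_x
    out_t = mod(Tensor(cur.transpose(0, 2, 1)[None]),
                Tensor(prev.transpose(0, 2, 1)[None])).numpy()
    np.testing.assert_allclose(out_t, out.transpose(0, 1, 3, 2), atol=1e-10)


# ----------------------------------------------------- multiplier invariant
def collect_multipliers(model, image_a, image_b):
    """All attention multiplier fields (1 + two masks) of one forward pass."""
    mults = []
    feats_a, feats_b = model.extractor_a(image_a), model.extractor_b(image_b)
    previous = None
    for i in reversed(range(model.n_scales)):
        block = getattr(model, f"block{i}")
        fused_branches = []
        for b in range(model.n_branches):
            cm = getattr(block, f"cmam{b}")
            fa_n = cm.bn_a(feats_a[b][i])
            fb_n = cm.bn_b(feats_b[b][i])
            m_a, m_b = cm.masks(fa_n, fb_n)
            mults.append(1.0 + m_a.numpy() + m_b.numpy())
            fused_branches.append(getattr(block, f"branch_conv{b}")(
                cm(feats_a[b][i], feats_b[b][i])))
        f = ag.concat(fused_branches, axis=1)
        m_max, m_avg = block.cbam.masks(f)
        mults.append(1.0 + m_max.numpy() + m_avg.numpy())
        x = block.post_branch(block.cbam(fused_branches))
        if block.prev_channels is None:
            previous = x
            continue
        prev = ag.upsample_bilinear(previous, 2)
        prev = block.prev_conv2(block.prev_conv1(block.prev_conv0(prev)))
        fcat = ag.concat([x, prev], axis=1)
        m_x, m_y = block.csam.masks(fcat)
        mults.append(1.0 + m_x.numpy() + m_y.numpy())
        previous = block.post_scale(block.csam(x, prev))
    return mults


def test_attention_multipliers_in_open_interval(rng):
    model = FusionModel(channels=(2, 2, 4, 4, 4), seed=21)
    model.train()
    for _ in range(5):
        a = Tensor(rng.random((1, 1, 48, 48)))
        b = Tensor(rng.random((1, 1, 48, 48)))
        for m in collect_multipliers(model, a, b):
            assert m.min() > 1.0 and m.max() < 3.0


# ------------------------------------------------------------ fusion blocks
def test_model_instantiates_five_fusion_blocks(micro_model):
    assert len(micro_model.fusion_blocks) == 5


def test_coarsest_block_has_no_cross_scale_processing(micro_model):
    coarsest = micro_model.fusion_blocks[-1]
    assert coarsest.prev_channels is None
    assert not hasattr(coarsest, "csam")


def test_fusion_block_zero_weights_give_zero_output(rng):
    block = FusionBlock(2, None, rng=np.random.default_rng(1))
    block.eval()
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    feats = [Tensor(rng.random((1, 2, 8, 8))) for _ in range(3)]
    out = block(feats, [Tensor(rng.random((1, 2, 8, 8))) for _ in range(3)])
    np.testing.assert_allclose(out.numpy(), 0.0)


def test_fusion_block_rejects_missing_branches(rng):
    block = FusionBlock(2, None, rng=np.random.default_rng(1))
    with pytest.raises(ValueError):
        block([Tensor(rng.random((1, 2, 4, 4)))] * 2,
              [Tensor(rng.random((1, 2, 4, 4)))] * 2)


# ----------------------------------------------------------- reconstruction
def test_reconstruction_output_in_unit_interval(rng):
    head = ReconstructionHead(4, rng=np.random.default_rng(2)).eval()
    out = head(Tensor(rng.normal(size=(1, 4, 16, 16)) * 5)).numpy()
    assert out.shape == (1, 1, 16, 16)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_reconstruction_zero_weights_give_half_gray():
    head = ReconstructionHead(4, rng=np.random.default_rng(2)).eval()
    for p in head.parameters():
        p.data = np.zeros_like(p.data)
    out = head(Tensor(np.random.default_rng(0).random((1, 4, 8, 8))))
    np.testing.assert_allclose(out.numpy(), 0.5)


# -------------------------------------------------------------- end-to-end
def test_fuse_images_deterministic_and_shape(phantom_pair_64, micro_model):
    f1 = fuse_images(phantom_pair_64.image_a, phantom_pair_64.image_b,
                     micro_model)
    f2 = fuse_images(phantom_pair_64.image_a, phantom_pair_64.image_b,
                     micro_model)
    assert f1.shape == phantom_pair_64.image_a.shape
    assert np.array_equal(f1, f2)
    assert f1.min() >= 0.0 and f1.max() <= 1.0


def test_fuse_images_rejects_unregistered_sizes(micro_model):
    with pytest.raises(ValueError):
        fuse_images(np.zeros((32, 32)), np.zeros((64, 64)), micro_model)


def test_every_parameter_receives_gradient(rng):
    """Gradient leak: each trainable parameter gets a nonzero gradient for at
    least one random input batch (gradients accumulate across batches)."""
    model = FusionModel(channels=(4, 8, 8, 16, 16), seed=13)
    model.train()
    for _ in range(3):
        out = model(Tensor(rng.random((2, 1, 48, 48))),
                    Tensor(rng.random((2, 1, 48, 48))))
        ((out - 0.3) ** 2).mean().backward()
    missing = [n for n, p in model.named_parameters()
               if p.grad is None or not np.any(p.grad)]
    assert missing == []
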