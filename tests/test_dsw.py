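"""Dynamic Swin Window: partition geometry, masked attention vs dense oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dense_attention_oracle, grouped_attention_oracle

from awpfnet import nn
from awpfnet.dsw import (DSWConfig, DSWStack, WindowAttention, dsw_apply,
                         partition_windows, reverse_windows, select_shift,
                         select_window_size, window_attention)


# ---------------------------------------------------------------------------
# window size / shift rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("level,strategy,expected", [
    (1, "mix", 7), (2, "mix", 5),
    (1, "fixed5", 5), (2, "fixed5", 5),
    (1, "fixed7", 7), (2, "fixed7", 7),
])
def test_window_size_rule(level, strategy, expected):
    assert select_window_size(level, strategy) == expected


@pytest.mark.parametrize("level", [0, 3, -1])
def test_window_size_rejects_levels_outside_pyramid(level):
    with pytest.raises(ValueError):
        select_window_size(level, "mix")


@pytest.mark.parametrize("block,H,W,cap,expected", [
    (0, 14, 14, 3, 0), (2, 14, 14, 3, 0),      # even blocks unshifted
    (1, 14, 14, 3, 3), (3, 14, 14, 3, 3),
    (1, 4, 4, 3, 2),                            # capped by half the side
    (1, 1, 9, 3, 0),
])
def test_shift_rule(block, H, W, cap, expected):
    assert select_shift(block, H, W, cap) == expected


# ---------------------------------------------------------------------------
# partition / reverse
# ---------------------------------------------------------------------------

def test_partition_counts_and_padding_for_14x14_window7():
    F = np.arange(1 * 2 * 14 * 14, dtype=np.float32).reshape(1, 2, 14, 14)
    ws = partition_windows(F, 7, 0)
    assert ws.num_windows == 4
    assert ws.tokens.shape == (4, 49, 2)
    assert ws.pad == (0, 0)
    assert ws.valid_mask.all()


def test_partition_pads_7x7_map_to_10x10_with_window5():
    F = np.ones((1, 1, 7, 7), dtype=np.float32)
    ws = partition_windows(F, 5, 0)
    assert ws.pad == (3, 3)
    assert ws.num_windows == 4
    assert int((~ws.valid_mask).sum()) == 100 - 49  # 51 padded cells


def test_partition_roundtrip_exact_over_grid(rng):
    for side_h, side_w in [(5, 5), (6, 9), (8, 8), (11, 5), (16, 13)]:
        F = rng.integers(0, 100, (2, 3, side_h, side_w)).astype(np.float32)
        for M in range(1, 9):
            for shift in range(M):
                ws = partition_windows(F, M, shift)
                assert np.array_equal(reverse_windows(ws), F), (M, shift)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    H=st.integers(3, 14), W=st.integers(3, 14),
    M=st.integers(1, 8), data=st.data(),
)
def test_partition_roundtrip_property(H, W, M, data):
    """reverse(partition(F, M, s)) == F for any map, window and shift."""
    shift = data.draw(st.integers(0, M - 1))
    rng = np.random.default_rng(H * 1000 + W * 10 + M)
    F = rng.integers(0, 100, (1, 2, H, W)).astype(np.float32)
    ws = partition_windows(F, M, shift)
    assert np.array_equal(reverse_windows(ws), F)
    assert int(ws.valid_mask.sum()) == H * W  # every real cell valid once


def test_partition_rejects_bad_window_and_shift():
    F = np.zeros((1, 1, 8, 8), np.float32)
    with pytest.raises(ValueError):
        partition_windows(F, 0, 0)
    with pytest.raises(ValueError):
        partition_windows(F, 4, 4)


# ---------------------------------------------------------------------------
# dense attention oracles
# ---------------------------------------------------------------------------

def identity_attention(channels, window, heads=1):
    """Attention with identity q/k/v/out projections and zero bias table."""
    attn = WindowAttention(channels, window, heads,
                           rng=np.random.default_rng(0))
    eye = np.eye(channels, dtype=np.float32)
    for lin in (attn.q, attn.k, attn.v, attn.proj):
        lin.weight.data = eye.copy()
        if lin.bias is not None:
            lin.bias.data[:] = 0
    attn.rel_bias_table.data[:] = 0
    return attn


def test_single_token_attention_returns_value_row():
    attn = identity_attention(2, 1)
    tok = np.array([[[3.0, -1.0]]], dtype=np.float32)
    out = attn(nn.Tensor(tok)).numpy()
    assert np.allclose(out, tok, atol=1e-6)


def test_identical_keys_give_uniform_mean_of_values(rng):
    attn = identity_attention(4, 2)
    toks = rng.standard_normal((1, 4, 4)).astype(np.float32)
    # make all key rows identical by zeroing the key projection
    attn.k.weight.data[:] = 0
    out = attn(nn.Tensor(toks)).numpy()
    assert np.allclose(out, toks.mean(axis=1, keepdims=True), atol=1e-5)


def test_window_attention_matches_dense_oracle(rng):
    attn = WindowAttention(2, window=2, num_heads=1, rng=rng)
    toks = rng.standard_normal((1, 4, 2)).astype(np.float32)
    out = attn(nn.Tensor(toks)).numpy()[0]
    assert np.allclose(out, dense_attention_oracle(toks[0], attn), atol=1e-6)


def test_masked_windowed_attention_matches_neighbourhood_oracle(rng):
    """Shift and padding masks reproduce dense attention on the original
    window neighbourhoods for every map up to 8x8."""
    attn = WindowAttention(4, window=3, num_heads=2, rng=rng)
    for H in range(1, 9):
        for W in range(1, 9):
            F = rng.standard_normal((1, 4, H, W)).astype(np.float32)
            for shift in range(3):
                if shift and shift >= min(3, H // 2, W // 2):
                    continue
                ws = partition_windows(F, 3, shift)
                got = reverse_windows(window_attention(ws, attn))
                exp = grouped_attention_oracle(F, 3, shift, attn)
                assert np.allclose(got, exp, atol=1e-6), (H, W, shift)


def test_attention_rows_over_unmasked_keys_sum_to_one(rng):
    from awpfnet.dsw import attention_mask
    F = rng.standard_normal((1, 4, 7, 7)).astype(np.float32)
    ws = partition_windows(F, 3, 1)
    mask = attention_mask(ws)
    # softmax of arbitrary scores plus the mask must be row-stochastic
    # over the allowed keys for every valid (non-padded) query
    scores = np.random.default_rng(0).standard_normal((ws.num_windows, 9, 9))
    probs = np.exp(scores + mask)
    probs /= probs.sum(axis=-1, keepdims=True)
    allowed = mask == 0
    sums = (probs * allowed).sum(axis=-1)
    valid_rows = ws.valid_mask[:, :, 0]
    assert np.allclose(sums[valid_rows], 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def test_dsw_apply_upsamples_to_target(rng):
    x = rng.standard_normal((1, 16, 7, 7)).astype(np.float32)
    cfg = DSWConfig(num_heads=4)
    out = dsw_apply(x, (14, 14), level=2, cfg=cfg)
    assert out.shape == (1, 16, 14, 14)
    out = dsw_apply(rng.standard_normal((1, 16, 14, 14)).astype(np.float32),
                    (28, 28), level=1, cfg=cfg)
    assert out.shape == (1, 16, 28, 28)


def test_dsw_apply_identity_target_keeps_size(rng):
    stack = DSWStack(16, level=2, cfg=DSWConfig(num_heads=4), seed=0)
    stack.eval()
    x = rng.standard_normal((1, 16, 7, 7)).astype(np.float32)
    enhanced = stack(nn.Tensor(x)).numpy()
    out = dsw_apply(x, (7, 7), level=2, stack=stack)
    assert np.allclose(out.numpy(), enhanced, atol=1e-6)


def test_dsw_apply_rejects_degenerate_target(rng):
    with pytest.raises(ValueError):
        dsw_apply(rng.standard_normal((1, 16, 7, 7)).astype(np.float32),
                  (0, 5), level=2, cfg=DSWConfig(num_heads=4))


def test_dsw_stack_is_batch_permutation_equivariant(rng):
    stack = DSWStack(8, level=2, cfg=DSWConfig(num_heads=2), seed=0)
    stack.eval()
    x = rng.standard_normal((3, 8, 7, 7)).astype(np.float32)
    perm = np.array([2, 0, 1])
    a = stack(nn.Tensor(x)).numpy()[perm]
    b = stack(nn.Tensor(x[perm])).numpy()
    assert np.allclose(a, b, atol=1e-5)


def test_dsw_config_validation():
    with pytest.raises(ValueError):
        DSWConfig(depth=0)
    with pytest.raises(ValueError):
        DSWConfig(window_strategy="huge")
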