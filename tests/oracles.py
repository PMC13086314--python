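"""Independent straight-line oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorised code paths: attention
is computed densely in float64 with explicit Python loops over groups of
positions, and macro metrics with an explicit per-class loop.
"""

import numpy as np

from awpfnet.dsw import relative_position_index


def _proj(t, lin):
    out = t @ lin.weight.numpy().T
    if lin.bias is not None:
        out = out + lin.bias.numpy()
    return out


def dense_attention_oracle(tokens, attn):
    """Softmax attention for one full window, float64, no masking."""
    t = tokens.astype(np.float64)
    q, k, v = _proj(t, attn.q), _proj(t, attn.k), _proj(t, attn.v)
    h, d = attn.num_heads, attn.head_dim
    bias = attn.rel_bias_table.numpy()[relative_position_index(attn.window)]
    out = np.zeros_like(t)
    for head in range(h):
        sl = slice(head * d, (head + 1) * d)
        s = q[:, sl] @ k[:, sl].T / np.sqrt(d) + bias[:, :, head]
        e = np.exp(s - s.max(axis=1, keepdims=True))
        e /= e.sum(axis=1, keepdims=True)
        out[:, sl] = e @ v[:, sl]
    return out @ attn.proj.weight.numpy().T + attn.proj.bias.numpy()


def grouped_attention_oracle(F, M, shift, attn):
    """Dense attention restricted to the shifted-window neighbourhoods of
    the original (unrolled) map, computed position by position.

    A position (i, j) rolls to ((i-shift) mod H, (j-shift) mod W); its
    neighbourhood is the set of positions sharing its rolled window whose
    ordering was not wrapped by the roll (same side of the seam per axis).
    """
    _, C, H, W = F.shape
    t = F[0].reshape(C, H * W).T.astype(np.float64)
    q, k, v = _proj(t, attn.q), _proj(t, attn.k), _proj(t, attn.v)
    h, d = attn.num_heads, attn.head_dim
    table = attn.rel_bias_table.numpy()
    span = 2 * M - 1
    groups = {}
    for i in range(H):
        for j in range(W):
            ri, rj = (i - shift) % H, (j - shift) % W
            key = (ri // M, rj // M, i >= shift, j >= shift)
            groups.setdefault(key, []).append((i * W + j, (ri % M, rj % M)))
    out = np.zeros_like(t)
    for members in groups.values():
        idx = [m[0] for m in members]
        coords = [m[1] for m in members]
        for head in range(h):
            sl = slice(head * d, (head + 1) * d)
            s = q[idx][:, sl] @ k[idx][:, sl].T / np.sqrt(d)
            for a, (ra, ca) in enumerate(coords):
                for b, (rb, cb) in enumerate(coords):
                    s[a, b] += table[(ra - rb + M - 1) * span
                                     + (ca - cb + M - 1), head]
            e = np.exp(s - s.max(axis=1, keepdims=True))
            e /= e.sum(axis=1, keepdims=True)
            out[idx, sl.start:sl.stop] = e @ v[idx][:, sl]
    out = out @ attn.proj.weight.numpy().T + attn.proj.bias.numpy()
    return out.T.reshape(1, C, H, W)


def brute_force_macro(counts):
    """Independent per-class loop for Acc/MP/MR/MF (zero denominator -> 0)."""
    k = counts.shape[0]
    n = counts.sum()
    ps, rs, fs = [], [], []
    for i in range(k):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        ps.append(tp / (tp + fp) if tp + fp else 0.0)
        rs.append(tp / (tp + fn) if tp + fn else 0.0)
        fs.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
    return (np.trace(counts) / n, np.mean(ps), np.mean(rs), np.mean(fs))
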