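"""Dynamic Swin Window (DSW) blocks.

Windowed self-attention whose window size adapts to the pyramid level:
7x7 on the shallow level-1 map, 5x5 on the deeper level-2 map (the
"mix" strategy), so that windows never have to over-pad small maps.
Blocks alternate between regular and shifted window partitions; the
shift offset is capped at 3 and never exceeds half the map side.

The partition rolls the map cyclically by the shift, zero-pads
bottom/right to a multiple of the window size, and tiles.  Attention
inside each window adds a learned relative-position bias and masks out
(a) padded positions and (b) pairs of positions that were not spatially
contiguous before the cyclic roll, so shifted windows act on the real
neighbourhoods of the original map, not on wrap-around artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import FeatureMap

NEG_INF = -1e9

WINDOW_STRATEGIES = ("mix", "fixed5", "fixed7")


@dataclass
class DSWConfig:
    depth: int = 2                  # blocks per stack; >=2 needed for any shift
    window_strategy: str = "mix"
    mlp_ratio: float = 4.0
    shift_cap: int = 3
    num_heads: int = 8
    with_ffn: bool = True           # feed-forward sublayer in each block

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.window_strategy not in WINDOW_STRATEGIES:
            raise ValueError(
                f"window_strategy must be one of {WINDOW_STRATEGIES}, "
                f"got {self.window_strategy!r}")


def select_window_size(level: int, strategy: str = "mix") -> int:
    """Window side for a pyramid level: 7 for level 1, 5 for level 2 (mix)."""
    if level not in (1, 2):
        raise ValueError(f"level must be 1 or 2, got {level}")
    if strategy == "mix":
        return 7 if level == 1 else 5
    if strategy == "fixed5":
        return 5
    if strategy == "fixed7":
        return 7
    raise ValueError(f"unknown window strategy {strategy!r}")


def select_shift(block_index: int, Hi: int, Wi: int, cap: int = 3) -> int:
    """Shift offset: 0 on even blocks, min(cap, Hi//2, Wi//2) on odd blocks."""
    if block_index % 2 == 0:
        return 0
    return min(cap, Hi // 2, Wi // 2)


# ---------------------------------------------------------------------------
# window partition / reverse
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Tokens of an M x M window tiling plus the metadata to invert it."""

    tokens: np.ndarray              # (B * num_windows, M*M, C)
    grid: tuple[int, int]           # (rows, cols) of windows
    pad: tuple[int, int]            # bottom / right zero padding
    shift: int
    valid_mask: np.ndarray          # (num_windows, M*M, 1) bool, False on padding
    window: int
    batch: int
    orig_hw: tuple[int, int]
    group_ids: np.ndarray = field(repr=False, default=None)  # (num_windows, M*M)

    @property
    def num_windows(self) -> int:
        return self.grid[0] * self.grid[1]


def _partition_geometry(H: int, W: int, M: int, shift: int):
    """Validity + contiguity metadata shared by the array and Tensor paths."""
    pad_h = (-H) % M
    pad_w = (-W) % M
    Hp, Wp = H + pad_h, W + pad_w
    rows, cols = Hp // M, Wp // M

    # rolled row r < H came from original row (r + shift) % H; rows r < H-shift
    # kept their ordering (side 0), rows H-shift..H-1 wrapped around (side 1),
    # rows >= H are padding (side 2).  Same along columns.
    def side(idx: np.ndarray, size: int) -> np.ndarray:
        s = np.full(idx.shape, 2, dtype=np.int64)
        s[idx < size] = 1
        s[idx < size - shift] = 0
        return s

    rs = side(np.arange(Hp), H)
    cs = side(np.arange(Wp), W)
    ids = rs[:, None] * 3 + cs[None, :]                     # (Hp, Wp)
    valid = (rs[:, None] < 2) & (cs[None, :] < 2)           # (Hp, Wp)

    def tile(a: np.ndarray) -> np.ndarray:
        return (a.reshape(rows, M, cols, M)
                 .transpose(0, 2, 1, 3)
                 .reshape(rows * cols, M * M))

    return pad_h, pad_w, rows, cols, tile(ids), tile(valid)


def partition_windows(F, M: int, shift: int = 0) -> WindowSet:
    """Tile a (B, C, H, W) map into M x M windows after a cyclic roll.

    Accepts a :class:`FeatureMap` or a plain array; the stored metadata is
    sufficient for :func:`reverse_windows` to reconstruct the map exactly.
    """
    if M <= 0:
        raise ValueError(f"window size M must be positive, got {M}")
    if not 0 <= shift < M:
        raise ValueError(f"shift must satisfy 0 <= shift < M, got {shift}")
    if isinstance(F, FeatureMap):
        F = F.numpy()
    elif isinstance(F, nn.Tensor):
        F = F.numpy()
    F = np.asarray(F)
    B, C, H, W = F.shape
    pad_h, pad_w, rows, cols, group_ids, valid = _partition_geometry(H, W, M, shift)

    x = np.roll(F, (-shift, -shift), axis=(2, 3)) if shift else F
    if pad_h or pad_w:
        x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
    tokens = (x.reshape(B, C, rows, M, cols, M)
               .transpose(0, 2, 4, 3, 5, 1)
               .reshape(B * rows * cols, M * M, C))
    return WindowSet(tokens=tokens, grid=(rows, cols), pad=(pad_h, pad_w),
                     shift=shift, valid_mask=valid[:, :, None], window=M,
                     batch=B, orig_hw=(H, W), group_ids=group_ids)


def reverse_windows(ws: WindowSet) -> np.ndarray:
    """Invert :func:`partition_windows`, returning the (B, C, H, W) map."""
    rows, cols = ws.grid
    M, B = ws.window, ws.batch
    H, W = ws.orig_hw
    C = ws.tokens.shape[-1]
    x = (ws.tokens.reshape(B, rows, cols, M, M, C)
                  .transpose(0, 5, 1, 3, 2, 4)
                  .reshape(B, C, rows * M, cols * M))
    x = x[:, :, :H, :W]
    if ws.shift:
        x = np.roll(x, (ws.shift, ws.shift), axis=(2, 3))
    return np.ascontiguousarray(x)


def attention_mask(ws_or_geom, M: int | None = None) -> np.ndarray:
    """Additive (num_windows, M*M, M*M) mask: 0 where attention is allowed.

    A query may attend keys in the same contiguity group; padded queries
    fall back to attending other padded positions (always including
    themselves) so no softmax row is ever empty.
    """
    if isinstance(ws_or_geom, WindowSet):
        group_ids = ws_or_geom.group_ids
        valid = ws_or_geom.valid_mask[:, :, 0]
    else:
        group_ids, valid = ws_or_geom
    same = group_ids[:, :, None] == group_ids[:, None, :]
    allowed = same & (valid[:, None, :] | ~valid[:, :, None])
    return np.where(allowed, 0.0, NEG_INF).astype(np.float32)


# ---------------------------------------------------------------------------
# windowed multi-head attention with relative position bias
# ---------------------------------------------------------------------------

def relative_position_index(M: int) -> np.ndarray:
    """(M^2, M^2) index into a (2M-1)^2 bias table, one row per query."""
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M), indexing="ij"))
    flat = coords.reshape(2, -1)                 # (2, M^2)
    rel = flat[:, :, None] - flat[:, None, :]    # (2, M^2, M^2)
    rel = rel + (M - 1)                          # to [0, 2M-2]
    return rel[0] * (2 * M - 1) + rel[1]


class WindowAttention(nn.Module):
    """Multi-head self-attention inside M x M windows.

    Scores are QK^T / sqrt(d_k) plus a learned relative-position bias
    indexed by the in-window offset; the additive mask from the window
    partition is applied before the softmax.
    """

    def __init__(self, channels: int, window: int, num_heads: int = 8, *, rng):
        super().__init__()
        if channels % num_heads:
            raise ValueError(f"channels ({channels}) must be divisible by "
                             f"num_heads ({num_heads})")
        self.channels = channels
        self.window = window
        self.num_heads = num_heads
        self.head_dim = channels // num_heads
        self.scale = self.head_dim ** -0.5
        self.q = nn.Linear(channels, channels, rng=rng)
        # a key bias is dead under softmax (constant shift per query row)
        self.k = nn.Linear(channels, channels, bias=False, rng=rng)
        self.v = nn.Linear(channels, channels, rng=rng)
        self.proj = nn.Linear(channels, channels, rng=rng)
        table_size = (2 * window - 1) ** 2
        self.rel_bias_table = nn.Parameter(
            nn.trunc_normal(rng, (table_size, num_heads)))
        self.rel_index = relative_position_index(window)

    def forward(self, tokens: nn.Tensor, mask: np.ndarray | None = None) -> nn.Tensor:
        """tokens: (B * num_windows, N, C); mask: (num_windows, N, N) additive."""
        BW, N, C = tokens.shape
        h, d = self.num_heads, self.head_dim

        def heads(t: nn.Tensor) -> nn.Tensor:
            return t.reshape(BW, N, h, d).transpose((0, 2, 1, 3))

        q = heads(self.q(tokens)) * self.scale
        k = heads(self.k(tokens))
        v = heads(self.v(tokens))
        scores = q @ k.transpose((0, 1, 3, 2))              # (BW, h, N, N)
        bias = nn.take_rows(self.rel_bias_table, self.rel_index)  # (N, N, h)
        scores = scores + bias.transpose((2, 0, 1)).reshape(1, h, N, N)
        if mask is not None:
            nw = mask.shape[0]
            scores = scores.reshape(BW // nw, nw, h, N, N)
            scores = nn.add_constant(scores, mask[None, :, None])
            scores = scores.reshape(BW, h, N, N)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(BW, N, C)
        return self.proj(out)


def window_attention(ws: WindowSet, params: WindowAttention) -> WindowSet:
    """Apply windowed attention to a :class:`WindowSet`, metadata preserved."""
    if ws.tokens.shape[-1] != params.num_heads * params.head_dim:
        raise ValueError("token channel dim must equal num_heads * head_dim")
    out = params(nn.Tensor(ws.tokens), attention_mask(ws))
    return WindowSet(tokens=out.numpy(), grid=ws.grid, pad=ws.pad,
                     shift=ws.shift, valid_mask=ws.valid_mask,
                     window=ws.window, batch=ws.batch, orig_hw=ws.orig_hw,
                     group_ids=ws.group_ids)


# ---------------------------------------------------------------------------
# transformer block / stack operating on feature maps
# ---------------------------------------------------------------------------

def _partition_tensor(x: nn.Tensor, M: int, shift: int):
    """Autodiff-path window partition; mirrors :func:`partition_windows`."""
    B, C, H, W = x.shape
    pad_h, pad_w, rows, cols, group_ids, valid = _partition_geometry(H, W, M, shift)
    y = x.roll2d(-shift, -shift).pad2d(pad_h, pad_w)
    tokens = (y.reshape(B, C, rows, M, cols, M)
               .transpose((0, 2, 4, 3, 5, 1))
               .reshape(B * rows * cols, M * M, C))
    mask = attention_mask((group_ids, valid))
    return tokens, mask, (rows, cols)


def _reverse_tensor(tokens: nn.Tensor, grid, M: int, shift: int, B: int,
                    H: int, W: int) -> nn.Tensor:
    rows, cols = grid
    C = tokens.shape[-1]
    y = (tokens.reshape(B, rows, cols, M, M, C)
               .transpose((0, 5, 1, 3, 2, 4))
               .reshape(B, C, rows * M, cols * M))
    return y.crop2d(H, W).roll2d(shift, shift)


class DSWBlock(nn.Module):
    """Pre-norm windowed-attention block with optional feed-forward."""

    def __init__(self, channels: int, window: int, block_index: int,
                 cfg: DSWConfig, *, rng):
        super().__init__()
        self.window = window
        self.block_index = block_index
        self.cfg = cfg
        self.norm1 = nn.LayerNorm(channels)
        self.attn = WindowAttention(channels, window, cfg.num_heads, rng=rng)
        if cfg.with_ffn:
            hidden = int(channels * cfg.mlp_ratio)
            self.norm2 = nn.LayerNorm(channels)
            self.fc1 = nn.Linear(channels, hidden, rng=rng)
            self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        B, C, H, W = x.shape
        shift = select_shift(self.block_index, H, W, self.cfg.shift_cap)
        M = self.window

        seq = x.reshape(B, C, H * W).transpose((0, 2, 1))   # (B, HW, C)
        t = self.norm1(seq)
        m = t.transpose((0, 2, 1)).reshape(B, C, H, W)
        tokens, mask, grid = _partition_tensor(m, M, shift)
        tokens = self.attn(tokens, mask)
        x = x + _reverse_tensor(tokens, grid, M, shift, B, H, W)

        if self.cfg.with_ffn:
            seq = x.reshape(B, C, H * W).transpose((0, 2, 1))
            t = self.fc2(self.fc1(self.norm2(seq)).gelu())
            x = x + t.transpose((0, 2, 1)).reshape(B, C, H, W)
        return x


class DSWStack(nn.Module):
    """``depth`` DSW blocks at one pyramid level, all sharing one window size."""

    def __init__(self, channels: int, level: int, cfg: DSWConfig | None = None,
                 *, rng=None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or DSWConfig()
        self.level = level
        self.window = select_window_size(level, cfg.window_strategy)
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.blocks = [DSWBlock(channels, self.window, i, cfg, rng=rng)
                       for i in range(cfg.depth)]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        for block in self.blocks:
            x = block(x)
        return x


def dsw_apply(F, target_hw: tuple[int, int], level: int,
              cfg: DSWConfig | None = None, stack: DSWStack | None = None,
              seed: int = 0) -> FeatureMap:
    """Enhance a pyramid map with DSW blocks, then upsample to ``target_hw``.

    The map is processed at its native resolution and only afterwards
    bilinearly interpolated to the target size of the shallower level.
    """
    th, tw = target_hw
    if th < 1 or tw < 1:
        raise ValueError(f"target size must be at least (1, 1), got {target_hw}")
    if isinstance(F, FeatureMap):
        x, lvl = F.data, F.level
    else:
        x, lvl = F, level
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x))
    if stack is None:
        stack = DSWStack(x.shape[1], level, cfg, seed=seed)
        stack.eval()
    enhanced = stack(x)
    out = nn.upsample_bilinear(enhanced, (th, tw))
    return FeatureMap(out, level=max(level - 1, 0))
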