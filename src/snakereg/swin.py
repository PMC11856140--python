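"""3-D shifted-window transformer primitives.

Patch embedding, window partitioning with cyclic shifts, window multi-head
self-attention (W-MSA / SW-MSA) with relative position bias, the pre-norm
residual swin block, and patch merging / expanding.  Token grids are stored
channels-last, ``(d', h', w', C)``; grids that do not divide the window are
right-padded for attention and the padding is masked out and cropped away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import LayerNorm, Linear, Module, Parameter

NEG_INF = -1e9


@dataclass
class SwinConfig:
    """Width/depth of the hierarchical encoder-decoder backbone.

    ``embed_dim`` is the token width C after patch embedding; stage ``i``
    operates at width ``C * 2**i``.  ``window`` is the (d, h, w) attention
    window at full token resolution; it is clipped per-stage to the grid.
    """

    embed_dim: int = 48
    depths: tuple[int, ...] = (2, 2, 4, 2)
    heads: tuple[int, ...] = (4, 4, 8, 8)
    window: tuple[int, int, int] = (2, 4, 4)
    mlp_ratio: float = 4.0
    rel_bias: bool = True
    patch_size: int = 4

    def __post_init__(self):
        self.depths = tuple(self.depths)
        self.heads = tuple(self.heads)
        self.window = tuple(self.window)
        if len(self.depths) != len(self.heads):
            raise ValueError("depths and heads must have equal length")
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        for i, h in enumerate(self.heads):
            if (self.embed_dim * 2**i) % h:
                raise ValueError(f"heads[{i}]={h} does not divide stage width "
                                 f"{self.embed_dim * 2**i}")

    @property
    def n_stages(self) -> int:
        return len(self.depths)


@dataclass
class TokenGrid:
    """Tokens on a coarse 3-D grid with its downsampling level vs the input."""

    tokens: Tensor  # (d', h', w', C)
    level: int      # spatial stride relative to the input volume

    @property
    def grid_shape(self):
        return self.tokens.shape[:3]

    @property
    def channels(self):
        return self.tokens.shape[3]


# ---------------------------------------------------------------------------
# window bookkeeping

def _pad_sizes(shape, window):
    return tuple((w - s % w) % w for s, w in zip(shape, window))


def clip_window(window, grid_shape):
    """Shrink the window to the grid where the grid is smaller."""
    return tuple(min(w, s) for w, s in zip(window, grid_shape))


def window_partition(x: Tensor, window, shift) -> Tensor:
    """Cyclic shift, right-pad to window multiples and tile: (nW, T, C)."""
    D, H, W, C = x.shape
    if any(shift):
        x = ad.roll(x, tuple(-s for s in shift), (0, 1, 2))
    pd, ph, pw = _pad_sizes((D, H, W), window)
    if pd or ph or pw:
        x = ad.pad(x, [(0, pd), (0, ph), (0, pw), (0, 0)])
    Dp, Hp, Wp = D + pd, H + ph, W + pw
    wd, wh, ww = window
    x = ad.reshape(x, (Dp // wd, wd, Hp // wh, wh, Wp // ww, ww, C))
    x = ad.transpose(x, (0, 2, 4, 1, 3, 5, 6))
    return ad.reshape(x, (-1, wd * wh * ww, C))


def window_reverse(wins: Tensor, grid_shape, window, shift) -> Tensor:
    """Exact inverse of :func:`window_partition` (crop + reverse shift)."""
    D, H, W = grid_shape
    pd, ph, pw = _pad_sizes(grid_shape, window)
    Dp, Hp, Wp = D + pd, H + ph, W + pw
    wd, wh, ww = window
    C = wins.shape[-1]
    x = ad.reshape(wins, (Dp // wd, Hp // wh, Wp // ww, wd, wh, ww, C))
    x = ad.transpose(x, (0, 3, 1, 4, 2, 5, 6))
    x = ad.reshape(x, (Dp, Hp, Wp, C))
    x = x[:D, :H, :W, :]
    if any(shift):
        x = ad.roll(x, tuple(shift), (0, 1, 2))
    return x


def attention_mask(grid_shape, window, shift) -> np.ndarray | None:
    """Additive (nW, 1, T, T) mask preventing attention across wrapped
    shift boundaries and onto padded tokens; None when nothing is masked."""
    pd, ph, pw = _pad_sizes(grid_shape, window)
    if not any(shift) and not (pd or ph or pw):
        return None
    padded = tuple(s + p for s, p in zip(grid_shape, (pd, ph, pw)))
    region = np.zeros(padded, dtype=np.int64)
    cnt = 0
    slices_per_axis = []
    for s, w, sh, p in zip(grid_shape, window, shift, (pd, ph, pw)):
        if sh:
            slices_per_axis.append((slice(0, s - w), slice(s - w, s - sh), slice(s - sh, s + p)))
        else:
            slices_per_axis.append((slice(0, s + p),))
    for sd in slices_per_axis[0]:
        for sh_ in slices_per_axis[1]:
            for sw_ in slices_per_axis[2]:
                region[sd, sh_, sw_] = cnt
                cnt += 1
    valid = np.zeros(padded, dtype=bool)
    valid[:grid_shape[0], :grid_shape[1], :grid_shape[2]] = True
    if any(shift):
        neg = tuple(-s for s in shift)
        region = np.roll(region, neg, (0, 1, 2))
        valid = np.roll(valid, neg, (0, 1, 2))

    def tile(arr):
        wd, wh, ww = window
        a = arr.reshape(padded[0] // wd, wd, padded[1] // wh, wh, padded[2] // ww, ww)
        return a.transpose(0, 2, 4, 1, 3, 5).reshape(-1, wd * wh * ww)

    reg = tile(region)
    val = tile(valid)
    mask = np.where(reg[:, None, :] != reg[:, :, None], NEG_INF, 0.0)
    mask = np.where(~val[:, None, :], NEG_INF, mask)  # padded keys never attended
    # padded queries: leave at least the diagonal unmasked so softmax is defined
    T = mask.shape[-1]
    mask[:, np.arange(T), np.arange(T)] = 0.0
    return mask[:, None, :, :].astype(np.float32)


# ---------------------------------------------------------------------------
# modules

def _rel_index(window, table_window=None) -> np.ndarray:
    """Relative-position index of a (possibly clipped) window into the bias
    table built for ``table_window``."""
    td, th, tw = table_window or window
    wd, wh, ww = window
    coords = np.stack(np.meshgrid(np.arange(wd), np.arange(wh), np.arange(ww),
                                  indexing="ij")).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (3, T, T)
    rel = rel + np.array([td - 1, th - 1, tw - 1])[:, None, None]
    return (rel[0] * (2 * th - 1) * (2 * tw - 1) + rel[1] * (2 * tw - 1) + rel[2])


class WindowAttention(Module):
    """Multi-head scaled dot-product attention within (shifted) windows."""

    def __init__(self, dim: int, heads: int, window, rng: np.random.Generator,
                 rel_bias: bool = True):
        super().__init__()
        if dim % heads:
            raise ValueError(f"heads={heads} must divide dim={dim}")
        self.dim, self.heads = dim, heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.window = tuple(window)
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = rel_bias
        if rel_bias:
            wd, wh, ww = self.window
            n = (2 * wd - 1) * (2 * wh - 1) * (2 * ww - 1)
            self.bias_table = Parameter(rng.normal(0.0, 0.02, size=(n, heads)))
            self._idx_cache: dict[tuple, np.ndarray] = {}

    def forward(self, wins: Tensor, mask: np.ndarray | None = None,
                window=None) -> Tensor:
        nW, T, C = wins.shape
        window = tuple(window or self.window)
        qkv = ad.reshape(self.qkv(wins), (nW, T, 3, self.heads, self.head_dim))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, nW, heads, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), self.scale)
        if self.rel_bias:
            if window not in self._idx_cache:
                self._idx_cache[window] = _rel_index(window, self.window).reshape(-1)
            bias = ad.take(self.bias_table, self._idx_cache[window], axis=0)  # (T*T, heads)
            bias = ad.transpose(ad.reshape(bias, (T, T, self.heads)), (2, 0, 1))
            logits = ad.add(logits, bias)
        if mask is not None:
            logits = ad.add(logits, mask)
        attn = ad.softmax(logits, axis=-1)
        out = ad.matmul(attn, v)                                     # (nW, heads, T, hd)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (nW, T, C))
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(ad.gelu(self.fc1(x)))


class SwinBlock(Module):
    """Pre-norm residual block: x + (S)W-MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, window, rng, shifted: bool,
                 mlp_ratio: float = 4.0, rel_bias: bool = True):
        super().__init__()
        self.window = tuple(window)
        self.shifted = shifted
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rng, rel_bias)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor) -> Tensor:
        grid_shape = x.shape[:3]
        window = clip_window(self.window, grid_shape)
        shift = tuple(w // 2 if (self.shifted and g > w) else 0
                      for w, g in zip(window, grid_shape))
        mask = attention_mask(grid_shape, window, shift)
        h = window_partition(self.norm1(x), window, shift)
        h = self.attn(h, mask, window)
        x = ad.add(x, window_reverse(h, grid_shape, window, shift))
        return ad.add(x, self.mlp(self.norm2(x)))


class PatchEmbed(Module):
    """Split the stacked (moving, fixed) pair into 2 x 4 x 4 x 4 patches and
    project each flattened patch (128 values) to C channels."""

    def __init__(self, embed_dim: int, rng, patch_size: int = 4):
        super().__init__()
        self.patch = patch_size
        self.proj = Linear(2 * patch_size**3, embed_dim, rng)
        self.norm = LayerNorm(embed_dim)

    def forward(self, pair: Tensor) -> TokenGrid:
        if pair.ndim != 4 or pair.shape[0] != 2:
            raise ValueError("patch embedding needs a (2, D, H, W) moving+fixed pair")
        p = self.patch
        C2, D, H, W = pair.shape
        pads = [(0, (p - s % p) % p) for s in (D, H, W)]
        if any(hi for _, hi in pads):
            pair = ad.pad(pair, [(0, 0)] + pads)
            _, D, H, W = pair.shape
        x = ad.reshape(pair, (2, D // p, p, H // p, p, W // p, p))
        x = ad.transpose(x, (1, 3, 5, 0, 2, 4, 6))
        x = ad.reshape(x, (D // p, H // p, W // p, 2 * p**3))
        return TokenGrid(self.norm(self.proj(x)), level=p)


class PatchMerge(Module):
    """2x downsampling: concatenate 2x2x2 token neighbourhoods (8C) in
    (d, h, w) scan order and project to 2C."""

    def __init__(self, dim: int, rng):
        super().__init__()
        self.norm = LayerNorm(8 * dim)
        self.reduction = Linear(8 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        D, H, W, C = x.shape
        pads = [(0, s % 2) for s in (D, H, W)]
        if any(hi for _, hi in pads):
            x = ad.pad(x, pads + [(0, 0)])
            D, H, W, C = x.shape
        parts = [x[dz::2, dy::2, dx::2, :]
                 for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
        cat = ad.concat(parts, axis=-1)
        return self.reduction(self.norm(cat))


class PatchExpand(Module):
    """2x upsampling: project C -> 8 * (C/2) and redistribute the factor-8
    channel block into a 2x2x2 spatial neighbourhood at C/2 channels."""

    def __init__(self, dim: int, rng):
        super().__init__()
        if dim % 2:
            raise ValueError("patch expansion needs an even channel count")
        self.expand = Linear(dim, 4 * dim, rng, bias=False)
        self.norm = LayerNorm(dim // 2)

    def forward(self, x: Tensor, out_shape=None) -> Tensor:
        D, H, W, C = x.shape
        h = ad.reshape(self.expand(x), (D, H, W, 2, 2, 2, C // 2))
        h = ad.transpose(h, (0, 3, 1, 4, 2, 5, 6))
        h = ad.reshape(h, (2 * D, 2 * H, 2 * W, C // 2))
        if out_shape is not None:
            h = h[:out_shape[0], :out_shape[1], :out_shape[2], :]
        return self.norm(h)
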