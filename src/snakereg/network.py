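"""The deformable-registration network.

A hierarchical shifted-window transformer encoder-decoder over the stacked
(moving, fixed) pair, with:

* a convolutional stem providing full-resolution (``stem_channels``) and
  half-resolution (``C/2``) skip features,
* plain token skips at the deeper decoder stages and a multi-fusion dense
  skip at the shallowest one (VGG-style downsampling branches pull the stem
  features down to token resolution before fusion),
* a two-stage convolutional head that restores the ``C``-channel /4-scale
  token map to full resolution — a standard Conv3D block, then a dynamic
  snake convolution block, each gated by concurrent spatial & channel
  squeeze-and-excitation (scSE) — and
* a zero-initialized 3-channel convolution emitting the displacement field,
  so an untrained network starts exactly at the identity transform.

All shapes divisible by 4 from 16^3 upward are supported (odd token grids
are padded and cropped internally).
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import DisplacementField, Volume3D, warp_volume
from .nn import Adam, Conv3d, Linear, Module, make_norm3d
from .snake import DSConv3d, SnakeKernelSpec
from .swin import PatchEmbed, PatchExpand, PatchMerge, SwinBlock, SwinConfig, TokenGrid


@dataclass
class NetworkConfig:
    swin: SwinConfig = field(default_factory=SwinConfig)
    snake: SnakeKernelSpec = field(default_factory=SnakeKernelSpec)
    stem_channels: int = 16
    head_channels: int = 16
    dense_skip_depth: int = 2   # number of VGG branches feeding the dense skip (0-2)
    norm: str = "batch"
    zero_init_head: bool = True
    flow_gain: float = 1.0      # fixed gain on the (zero-initialized) field head

    def __post_init__(self):
        if self.swin.embed_dim % 2:
            raise ValueError("embed_dim must be even (the half-resolution stem uses C/2)")
        if not 0 <= self.dense_skip_depth <= 2:
            raise ValueError("dense_skip_depth must be 0, 1 or 2")
        if self.stem_channels < 1 or self.head_channels < 1:
            raise ValueError("channel counts must be positive")

    @classmethod
    def small(cls) -> "NetworkConfig":
        """Desk-scale configuration used by the scaled-down training runs."""
        return cls(swin=SwinConfig(embed_dim=12, depths=(1, 1), heads=(2, 2),
                                   window=(2, 2, 2), mlp_ratio=2.0),
                   snake=SnakeKernelSpec(points_per_kernel=3),
                   stem_channels=6, head_channels=6)

    def to_dict(self) -> dict:
        return {"swin": asdict(self.swin), "snake": asdict(self.snake),
                "stem_channels": self.stem_channels, "head_channels": self.head_channels,
                "dense_skip_depth": self.dense_skip_depth, "norm": self.norm,
                "zero_init_head": self.zero_init_head, "flow_gain": self.flow_gain}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        swin = SwinConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in d.pop("swin", {}).items()})
        snake = SnakeKernelSpec(**d.pop("snake", {}))
        return cls(swin=swin, snake=snake, **d)


@dataclass
class RegistrationOutput:
    field: DisplacementField
    warped: Volume3D


class ConvBlock(Module):
    """Conv3D (k=3, stride 1, padding 1) + normalization + ReLU."""

    def __init__(self, cin, cout, rng, norm="batch"):
        super().__init__()
        self.conv = Conv3d(cin, cout, rng, k=3)
        self.norm = make_norm3d(norm, cout)

    def forward(self, x):
        return ad.relu(self.norm(self.conv(x)))


class SCSE(Module):
    """Concurrent spatial & channel squeeze-and-excitation, fused by max.

    The channel gate squeezes by global average pooling through a bottleneck
    MLP with sigmoid; the spatial gate is a sigmoid-activated 1x1x1
    convolution.  Output = max(channel-gated, spatially-gated) features.
    """

    def __init__(self, channels, rng, reduction: int = 2):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial = Conv3d(channels, 1, rng, k=1, padding=0)

    def forward(self, x):
        C = x.shape[0]
        squeeze = ad.reshape(ad.tmean(ad.reshape(x, (C, -1)), axis=1), (1, C))
        cgate = ad.sigmoid(self.fc2(ad.relu(self.fc1(squeeze))))
        cse = ad.mul(x, ad.reshape(cgate, (C, 1, 1, 1)))
        sgate = ad.sigmoid(self.spatial(x))                          # (1, D, H, W)
        sse = ad.mul(x, sgate)
        return ad.maximum(cse, sse)


class VGGBranch(Module):
    """Downsampling branch of the dense skip: per halving, two conv-norm-ReLU
    layers followed by 2x average pooling."""

    def __init__(self, cin, cout, n_pools, rng, norm="batch"):
        super().__init__()
        self.n_pools = n_pools
        blocks = []
        c = cin
        for _ in range(max(1, n_pools)):
            blocks.append(ConvBlock(c, cout, rng, norm))
            blocks.append(ConvBlock(cout, cout, rng, norm))
            c = cout
        self.blocks = blocks

    def forward(self, x):
        for i in range(0, len(self.blocks), 2):
            x = self.blocks[i](x)
            x = self.blocks[i + 1](x)
            if i // 2 < self.n_pools:
                x = ad.avg_pool2(x)
        return x


class DenseSkip(Module):
    """Multi-fusion dense skip: concatenate the current features with all
    (already resampled) branch features, then fuse with two Conv3D blocks."""

    def __init__(self, cin_total, cout, rng, norm="batch"):
        super().__init__()
        self.fuse1 = ConvBlock(cin_total, cout, rng, norm)
        self.fuse2 = ConvBlock(cout, cout, rng, norm)

    def forward(self, current, branches: list):
        x = ad.concat([current] + list(branches), axis=0) if branches else current
        return self.fuse2(self.fuse1(x))


def _tokens_to_grid(tokens: Tensor) -> Tensor:
    return ad.transpose(tokens, (3, 0, 1, 2))


def _grid_to_tokens(grid: Tensor) -> Tensor:
    return ad.transpose(grid, (1, 2, 3, 0))


class STUNetPlus(Module):
    """Registration network F_theta(I_f, I_m) -> displacement field."""

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        sw = self.cfg.swin
        C = sw.embed_dim
        norm = self.cfg.norm
        S = sw.n_stages

        # convolutional stem: full-res and half-res skip features
        self.stem_full = ConvBlock(2, self.cfg.stem_channels, rng, norm)
        self.stem_half = ConvBlock(self.cfg.stem_channels, C // 2, rng, norm)

        self.embed = PatchEmbed(C, rng, sw.patch_size)
        self.enc_stages = [
            [SwinBlock(C * 2**i, sw.heads[i], sw.window, rng, shifted=bool(b % 2),
                       mlp_ratio=sw.mlp_ratio, rel_bias=sw.rel_bias)
             for b in range(sw.depths[i])]
            for i in range(S)
        ]
        for i, stage in enumerate(self.enc_stages):
            setattr(self, f"enc{i}", stage)
        self.merges = [PatchMerge(C * 2**i, rng) for i in range(S - 1)]
        self.expands = [PatchExpand(C * 2**(i + 1), rng) for i in range(S - 1)]
        # plain token skips at decoder stages S-2 .. 1
        self.skip_fuse = [Linear(2 * C * 2**i, C * 2**i, rng) for i in range(1, S - 1)]
        self.dec_stages = [
            [SwinBlock(C * 2**i, sw.heads[i], sw.window, rng, shifted=bool(b % 2),
                       mlp_ratio=sw.mlp_ratio, rel_bias=sw.rel_bias)
             for b in range(sw.depths[i])]
            for i in range(S - 1)
        ]
        for i, stage in enumerate(self.dec_stages):
            setattr(self, f"dec{i}", stage)

        # multi-fusion dense skip at the shallowest decoder stage (/4 scale)
        depth = self.cfg.dense_skip_depth
        branch_ch = []
        if depth >= 1:
            self.vgg_half = VGGBranch(C // 2, C // 2, 1, rng, norm)  # /2 -> /4
            branch_ch.append(C // 2)
        if depth >= 2:
            self.vgg_full = VGGBranch(self.cfg.stem_channels, self.cfg.stem_channels,
                                      2, rng, norm)                   # /1 -> /4
            branch_ch.append(self.cfg.stem_channels)
        self.dense = DenseSkip(2 * C + sum(branch_ch), C, rng, norm)

        # restoration head: Conv3D block then DSConv3D block, each + scSE
        hc = self.cfg.head_channels
        self.head_conv = ConvBlock(C + C // 2, C // 2, rng, norm)
        self.head_scse1 = SCSE(C // 2, rng)
        self.head_snake = DSConv3d(C // 2 + self.cfg.stem_channels, hc, rng, self.cfg.snake)
        self.head_snake_norm = make_norm3d(norm, hc)
        self.head_scse2 = SCSE(hc, rng)
        self.flow = Conv3d(hc, 3, rng, k=3, zero_init=self.cfg.zero_init_head)

    # -- forward pieces ------------------------------------------------------
    def conv_stem(self, pair: Tensor) -> tuple[Tensor, Tensor]:
        """Full-resolution (stem_channels) and half-resolution (C/2) features."""
        full = self.stem_full(pair)
        half = self.stem_half(ad.avg_pool2(full))
        return full, half

    def field_tensor(self, pair: Tensor, ablate: set[str] | None = None) -> Tensor:
        """Predict the displacement field (3, D, H, W) for a (2, D, H, W) pair.

        ``ablate`` names skip connections to zero out (sensitivity checks):
        'enc_skip_<i>', 'dense_enc0', 'dense_half', 'dense_full',
        'head_half', 'head_full'.
        """
        ablate = ablate or set()

        def gate(name, t):
            return ad.mul(t, 0.0) if name in ablate else t

        if pair.ndim != 4 or pair.shape[0] != 2:
            raise ValueError(f"expected a (2, D, H, W) pair, got {pair.shape}")
        D, H, W = pair.shape[1:]
        if D % 4 or H % 4 or W % 4 or min(D, H, W) < 16:
            raise ValueError("spatial dims must be divisible by 4 and >= 16")
        full, half = self.conv_stem(pair)

        tg = self.embed(pair)
        x = tg.tokens
        enc_feats = []
        shapes = []
        for i, stage in enumerate(self.enc_stages):
            for blk in stage:
                x = blk(x)
            enc_feats.append(x)
            shapes.append(x.shape[:3])
            if i < len(self.merges):
                x = self.merges[i](x)

        S = len(self.enc_stages)
        for i in range(S - 2, -1, -1):
            x = self.expands[i](x, out_shape=shapes[i])
            if i > 0:
                skip = gate(f"enc_skip_{i}", enc_feats[i])
                x = self.skip_fuse[i - 1](ad.concat([x, skip], axis=-1))
            else:
                cur = _tokens_to_grid(ad.concat([x, gate("dense_enc0", enc_feats[0])], axis=-1))
                branches = []
                if self.cfg.dense_skip_depth >= 1:
                    branches.append(gate("dense_half", self.vgg_half(half)))
                if self.cfg.dense_skip_depth >= 2:
                    branches.append(gate("dense_full", self.vgg_full(full)))
                x = _grid_to_tokens(self.dense(cur, branches))
            for blk in self.dec_stages[i]:
                x = blk(x)

        g = _tokens_to_grid(x)                                # (C, D/4, H/4, W/4)
        g = ad.upsample2_nearest(g)                           # /2
        g = ad.concat([g, gate("head_half", half)], axis=0)
        g = self.head_scse1(self.head_conv(g))
        g = ad.upsample2_nearest(g)                           # /1
        g = ad.concat([g, gate("head_full", full)], axis=0)
        g = self.head_scse2(ad.relu(self.head_snake_norm(self.head_snake(g))))
        phi = self.flow(g)
        if self.cfg.flow_gain != 1.0:
            phi = ad.mul(phi, self.cfg.flow_gain)
        return phi

    def forward(self, moving, fixed, ablate: set[str] | None = None) -> RegistrationOutput:
        """Full registration pass on numpy-backed volumes (no gradients)."""
        mov = moving if isinstance(moving, Volume3D) else Volume3D(np.asarray(moving))
        fix = fixed if isinstance(fixed, Volume3D) else Volume3D(np.asarray(fixed))
        if mov.shape != fix.shape:
            raise ValueError(f"moving {mov.shape} and fixed {fix.shape} shapes differ")
        shape = mov.shape
        pads = tuple((4 - s % 4) % 4 for s in shape)
        stacked = np.stack([mov.data, fix.data])
        if any(pads):  # right-pad with edge replication, crop the field after
            stacked = np.pad(stacked, ((0, 0),) + tuple((0, p) for p in pads), mode="edge")
        pair = Tensor(stacked)
        with ad.no_grad():
            phi = self.field_tensor(pair, ablate)
        vec = phi.data.astype(np.float64)[:, :shape[0], :shape[1], :shape[2]]
        fld = DisplacementField(vec)
        return RegistrationOutput(field=fld, warped=warp_volume(mov, fld, "trilinear"))


# ---------------------------------------------------------------------------
# checkpoints: a zip archive with the config (JSON) and parameters (npz)

def save_checkpoint(net: STUNetPlus, path, extra: dict | None = None):
    buf = _io.BytesIO()
    np.savez(buf, **net.state_dict())
    with zipfile.ZipFile(path, "w") as z:
        z.writestr("config.json", json.dumps(net.cfg.to_dict()))
        z.writestr("params.npz", buf.getvalue())
        z.writestr("extra.json", json.dumps(extra or {}))


def load_checkpoint(path) -> tuple[STUNetPlus, dict]:
    with zipfile.ZipFile(path) as z:
        cfg = NetworkConfig.from_dict(json.loads(z.read("config.json")))
        params = np.load(_io.BytesIO(z.read("params.npz")))
        extra = json.loads(z.read("extra.json"))
        net = STUNetPlus(cfg, seed=0)
        net.load_state_dict({k: params[k] for k in params.files})
    return net, extra
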