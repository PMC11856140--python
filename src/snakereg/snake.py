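"""3-D dynamic snake convolution (DSConv3D).

The standard k^3 kernel is *linearized* along each of the three axes into a
``points_per_kernel``-tap 1-D kernel whose sampling polyline bends laterally:
at step ``c`` from the center, the two lateral coordinates carry the running
sum of ``c`` learned per-step offsets, each squashed into
``[-max_step, +max_step]``.  Because offsets are fractional, samples are
gathered by trilinear interpolation.  With the default 9 taps and unit step
bound, the three axis-variants together can reach any position inside a
9 x 9 x 9 cube, while the cumulative (iterative) construction keeps the
sampling polyline connected — the receptive field follows elongated
structures instead of scattering.

A straightforward loop-based reference implementation
(:func:`dsconv3d_reference`) ships alongside the fast layer for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import Volume3D, trilinear_sample
from .nn import Conv3d, Module, Parameter

#: axis-variant names, in the order they are stored
AXES = ("x", "y", "z")
#: grid-axis index (in (d, h, w) order) each variant runs along
_ALONG = {"x": 2, "y": 1, "z": 0}


@dataclass
class SnakeKernelSpec:
    """Geometry of the linearized snake kernels.

    points_per_kernel: odd tap count per axis-variant (default 9 — the
        3x3x3 base kernel linearized, matching a 9x9x9 selectable field).
    max_step: bound on each per-step lateral offset (voxels).
    fusion: how the three axis-variant responses combine:
        "mean" (default), "sum", or "concat" (+ pointwise convolution).
    """

    points_per_kernel: int = 9
    max_step: float = 1.0
    fusion: str = "mean"

    def __post_init__(self):
        if self.points_per_kernel < 3 or self.points_per_kernel % 2 == 0:
            raise ValueError("points_per_kernel must be odd and >= 3")
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if self.fusion not in ("mean", "sum", "concat"):
            raise ValueError(f"unknown fusion {self.fusion!r}")

    @property
    def half(self) -> int:
        return (self.points_per_kernel - 1) // 2


@dataclass
class SnakeOffsets:
    """Per-voxel lateral offsets, shape (3 axes, 2 sides, half, 2 lateral, D, H, W).

    Side 0 is the minus side, side 1 the plus side.  For variant ``a`` the
    two lateral slots hold the offsets of the two grid axes other than
    ``_ALONG[a]``, in ascending (d, h, w) axis order.  All entries satisfy
    |delta| <= max_step.
    """

    delta: np.ndarray
    spec: SnakeKernelSpec

    def __post_init__(self):
        d = np.asarray(self.delta)
        if d.ndim != 7 or d.shape[:2] != (3, 2) or d.shape[2] != self.spec.half or d.shape[3] != 2:
            raise ValueError(f"bad offsets shape {d.shape}")
        if np.abs(d).max() > self.spec.max_step + 1e-6:
            raise ValueError("offsets exceed max_step")
        self.delta = d


def snake_positions(center, offsets, axis: str, spec: SnakeKernelSpec) -> np.ndarray:
    """Sampling positions of one snake kernel at one voxel (reference path).

    center: (d, h, w) coordinate of the kernel center.
    offsets: array (2, half, 2) — (side, step, lateral component), side 0 = minus.
    Returns (points_per_kernel, 3) positions ordered from -half to +half; the
    along-axis coordinate steps by +-1 per tap, the lateral coordinates carry
    the running sum of the first ``c`` offsets of that side, and the center
    carries zero offset.
    """
    offsets = np.asarray(offsets, dtype=np.float64)
    half = spec.half
    if offsets.shape != (2, half, 2):
        raise ValueError(f"offsets must have shape (2, {half}, 2), got {offsets.shape}")
    along = _ALONG[axis]
    lat = [i for i in range(3) if i != along]
    center = np.asarray(center, dtype=np.float64)
    pos = np.tile(center, (spec.points_per_kernel, 1))
    cum_minus = np.cumsum(offsets[0], axis=0)  # (half, 2)
    cum_plus = np.cumsum(offsets[1], axis=0)
    for c in range(1, half + 1):
        pos[half + c, along] += c
        pos[half - c, along] -= c
        for j, ax in enumerate(lat):
            pos[half + c, ax] += cum_plus[c - 1, j]
            pos[half - c, ax] += cum_minus[c - 1, j]
    return pos


def receptive_extent(spec: SnakeKernelSpec) -> tuple[int, int, int]:
    """Side lengths of the axis-aligned box bounding all reachable samples of
    one axis-variant, ordered (along-axis, lateral, lateral).

    Along the axis the kernel always spans ``points_per_kernel`` voxels; each
    lateral coordinate can accumulate at most ``max_step * half`` on either
    side, an integer-voxel extent of ``2 * ceil(max_step * half) + 1``.
    """
    along = spec.points_per_kernel
    lateral = 2 * math.ceil(spec.max_step * spec.half) + 1
    return (along, lateral, lateral)


def enumerate_saturated_positions(spec: SnakeKernelSpec) -> np.ndarray:
    """All sampling positions (relative to the center) for the three variants
    with every offset saturated at +max_step and at -max_step."""
    positions = []
    half = spec.half
    for axis in AXES:
        for sgn in (+1.0, -1.0):
            off = np.full((2, half, 2), sgn * spec.max_step)
            positions.append(snake_positions((0.0, 0.0, 0.0), off, axis, spec))
            # mixed saturation of the two lateral components
            off2 = off.copy()
            off2[:, :, 1] *= -1
            positions.append(snake_positions((0.0, 0.0, 0.0), off2, axis, spec))
    return np.concatenate(positions, axis=0)


class DSConv3d(Module):
    """The dynamic snake convolution layer.

    Offsets are predicted from the layer's own input features by a 3x3x3
    convolution (zero-initialized: training starts from straight, axis-aligned
    kernels) and squashed by ``max_step * tanh``.  Each axis-variant applies
    its own ``points_per_kernel`` taps with independent channel mixing; the
    three responses are fused per ``spec.fusion``.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 spec: SnakeKernelSpec | None = None):
        super().__init__()
        self.spec = spec or SnakeKernelSpec()
        self.cin, self.cout = cin, cout
        half = self.spec.half
        K = self.spec.points_per_kernel
        self.offset_conv = Conv3d(cin, 3 * 2 * half * 2, rng, k=3, zero_init=True)
        bound = np.sqrt(1.0 / (cin * K))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(3, cout, cin * K)))
        self.bias = Parameter(np.zeros(cout))
        if self.spec.fusion == "concat":
            self.fuse = Parameter(rng.uniform(-np.sqrt(1.0 / (3 * cout)),
                                              np.sqrt(1.0 / (3 * cout)),
                                              size=(3 * cout, cout)))

    # -- offsets -------------------------------------------------------------
    def predict_offsets(self, x: Tensor) -> Tensor:
        """Bounded offsets from input features: (3, 2, half, 2, D, H, W) tensor."""
        raw = self.offset_conv(x)
        spatial = x.shape[1:]
        squashed = ad.mul(ad.tanh(raw), self.spec.max_step)
        return ad.reshape(squashed, (3, 2, self.spec.half, 2) + tuple(spatial))

    # -- forward -------------------------------------------------------------
    def forward(self, x: Tensor, offsets: Tensor | None = None) -> Tensor:
        if offsets is None:
            offsets = self.predict_offsets(x)
        spatial = tuple(x.shape[1:])
        if tuple(offsets.shape[4:]) != spatial:
            raise ValueError(f"offsets spatial shape {offsets.shape[4:]} != input {spatial}")
        D, H, W = spatial
        N = D * H * W
        half = self.spec.half
        K = self.spec.points_per_kernel
        base = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float32) for n in spatial],
                                    indexing="ij")).reshape(3, N)  # (3, N)
        responses = []
        for ai, axis in enumerate(AXES):
            along = _ALONG[axis]
            # cumulative lateral offsets, (2 sides, half, 2, N)
            cum = ad.cumsum(ad.reshape(offsets[ai], (2, half, 2, N)), axis=1)
            coords = ad.snake_coords(cum, base, along, half)  # (K*N, 3), tap-major
            samples = ad.grid_sample(x, coords)       # (Cin, K*N)
            smat = ad.reshape(ad.transpose(ad.reshape(samples, (self.cin, K, N)),
                                           (1, 0, 2)), (K * self.cin, N))
            resp = ad.matmul(self._wmat(ai), smat)    # (cout, N)
            responses.append(resp)
        if self.spec.fusion == "mean":
            out = ad.mul(responses[0] + responses[1] + responses[2], 1.0 / 3.0)
        elif self.spec.fusion == "sum":
            out = responses[0] + responses[1] + responses[2]
        else:  # concat + pointwise
            cat = ad.concat(responses, axis=0)        # (3*cout, N)
            out = ad.matmul(ad.transpose(self.fuse, (1, 0)), cat)
        out = ad.add(out, ad.reshape(self.bias, (self.cout, 1)))
        return ad.reshape(out, (self.cout,) + spatial)

    def _wmat(self, ai: int) -> Tensor:
        """Axis ``ai`` mixing weights reshaped to contract (K*Cin, N) samples.

        ``self.weight[ai]`` is (cout, cin*K) with taps fastest; the sample
        matrix is (K, cin, N) flattened tap-major, so reorder to (cout, K*cin).
        """
        w = ad.reshape(self.weight[ai], (self.cout, self.cin, self.spec.points_per_kernel))
        return ad.reshape(ad.transpose(w, (0, 2, 1)), (self.cout, self.spec.points_per_kernel * self.cin))


def dsconv3d_reference(x: np.ndarray, layer: DSConv3d,
                       offsets: np.ndarray | None = None) -> np.ndarray:
    """Loop-based oracle: gather every snake position explicitly and sum
    weighted trilinear samples.  Independent of the vectorized layer path
    (uses :func:`snake_positions` / :func:`trilinear_sample`); small inputs only.
    """
    spec = layer.spec
    cin, D, H, W = x.shape
    if offsets is None:
        with ad.no_grad():
            offsets = layer.predict_offsets(Tensor(x)).data
    offsets = np.asarray(offsets, dtype=np.float64)
    K, half = spec.points_per_kernel, spec.half
    weight = layer.weight.data.reshape(3, layer.cout, cin, K)
    vols = [Volume3D(x[c]) for c in range(cin)]
    responses = np.zeros((3, layer.cout, D, H, W))
    for ai, axis in enumerate(AXES):
        for d in range(D):
            for h in range(H):
                for w in range(W):
                    off = offsets[ai, :, :, :, d, h, w]  # (2, half, 2)
                    pos = snake_positions((d, h, w), off, axis, spec)
                    samp = np.array([trilinear_sample(vols[c], pos) for c in range(cin)])
                    responses[ai, :, d, h, w] = np.einsum("ock,ck->o", weight[ai], samp)
    if spec.fusion == "mean":
        out = responses.mean(axis=0)
    elif spec.fusion == "sum":
        out = responses.sum(axis=0)
    else:
        cat = responses.reshape(3 * layer.cout, D, H, W)
        out = np.einsum("co,cdhw->odhw", layer.fuse.data, cat)
    return out + layer.bias.data[:, None, None, None]
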