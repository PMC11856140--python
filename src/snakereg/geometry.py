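"""Coordinate conventions, trilinear sampling, warping and Jacobian analysis.

Conventions used throughout the package:

* Grids are voxel-indexed, 0-based, axis order ``(d, h, w)``.
* Displacement fields are stored channel-first as ``(3, D, H, W)`` arrays with
  component order ``(du_d, du_h, du_w)`` in **voxel units**.
* Warping follows the resampling convention ``warped(p) = moving(p + u(p))``:
  the field lives on the fixed-image grid and points into the moving image.
* Sampling outside the volume border-clamps (replicates the edge value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid (an image such as I_m or I_f)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs a 3-D array, got rank {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap3D:
    """Integer anatomical label grid; background label is 0."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"LabelMap3D needs a 3-D array, got rank {labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("label map must be integer-valued")
            labels = labels.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class DisplacementField:
    """Per-voxel displacement u with components (du_d, du_h, du_w), voxel units."""

    vectors: np.ndarray  # (3, D, H, W)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError(f"DisplacementField needs shape (3, D, H, W), got {self.vectors.shape}")
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement components must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    @classmethod
    def zeros(cls, shape: tuple[int, int, int]) -> "DisplacementField":
        return cls(np.zeros((3,) + tuple(shape)))


@dataclass
class JacobianMap:
    """Local Jacobian determinants of the mapping p -> p + u(p)."""

    det: np.ndarray


def trilinear_sample(vol: Volume3D, positions) -> np.ndarray:
    """Sample a volume at fractional (d, h, w) positions by trilinear interpolation.

    The interpolation weight between a fractional coordinate ``a`` and a lattice
    coordinate ``a'`` is the separable hat ``b(a, a') = max(0, 1 - |a - a'|)``;
    the value is the weighted sum over the 8-corner neighbourhood.  Positions
    outside the volume are border-clamped.
    """
    positions = np.asarray(positions, dtype=np.float64)
    squeeze = positions.ndim == 1
    positions = np.atleast_2d(positions)
    if positions.shape[-1] != 3:
        raise ValueError("positions must have 3 components (d, h, w)")
    if not np.isfinite(positions).all():
        raise ValueError("positions must be finite")
    data = vol.data
    dims = np.array(data.shape, dtype=np.float64)
    cc = np.clip(positions, 0.0, dims - 1.0)
    i0 = np.clip(np.floor(cc).astype(np.int64), 0, (dims - 2).astype(np.int64).clip(min=0))
    f = cc - i0
    out = np.zeros(positions.shape[0])
    flat = data.reshape(-1)
    D, H, W = data.shape
    strides = np.array([H * W, W, 1])
    i0c = np.minimum(i0, np.array(data.shape) - 1)  # degenerate axes of size 1
    for cz in (0, 1):
        for cy in (0, 1):
            for cx in (0, 1):
                off = np.array([cz, cy, cx])
                idx = np.minimum(i0c + off, np.array(data.shape) - 1) @ strides
                w = (f[:, 0] if cz else 1 - f[:, 0]) * \
                    (f[:, 1] if cy else 1 - f[:, 1]) * \
                    (f[:, 2] if cx else 1 - f[:, 2])
                out += w * flat[idx]
    return out[0] if squeeze else out


def _base_grid(shape) -> np.ndarray:
    """Identity coordinate grid, shape (3, D, H, W)."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def warp_volume(moving, fld: DisplacementField, mode: str = "trilinear"):
    """Resample ``moving`` through a displacement field: out(p) = moving(p + u(p)).

    Label maps must use ``mode="nearest"`` so that labels are never averaged.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    is_labels = isinstance(moving, LabelMap3D)
    if is_labels and mode != "nearest":
        raise ValueError("label maps must be warped with mode='nearest'")
    data = moving.labels if is_labels else moving.data
    if data.shape != fld.shape:
        raise ValueError(f"field shape {fld.shape} does not match volume shape {data.shape}")
    pos = _base_grid(data.shape) + fld.vectors
    if mode == "nearest":
        idx = [np.clip(np.rint(pos[i]).astype(np.int64), 0, data.shape[i] - 1) for i in range(3)]
        out = data[idx[0], idx[1], idx[2]]
        return LabelMap3D(out) if is_labels else Volume3D(out, moving.spacing)
    flatpos = pos.reshape(3, -1).T
    out = trilinear_sample(moving, flatpos).reshape(data.shape)
    return Volume3D(out, moving.spacing)


def jacobian_determinant(fld: DisplacementField) -> JacobianMap:
    """det(I + grad u) per voxel; central differences inside, one-sided at borders."""
    if min(fld.shape) < 2:
        raise ValueError("Jacobian needs all dimensions >= 2")
    u = fld.vectors
    # grads[i][j] = d u_i / d x_j  (np.gradient: central interior, one-sided edges)
    grads = [np.gradient(u[i], axis=(0, 1, 2)) for i in range(3)]
    J = np.empty(fld.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            J[..., i, j] = grads[i][j]
            if i == j:
                J[..., i, j] += 1.0
    det = (J[..., 0, 0] * (J[..., 1, 1] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 1])
           - J[..., 0, 1] * (J[..., 1, 0] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 0])
           + J[..., 0, 2] * (J[..., 1, 0] * J[..., 2, 1] - J[..., 1, 1] * J[..., 2, 0]))
    return JacobianMap(det)


def pct_nondiffeomorphic(jac: JacobianMap) -> float:
    """Fraction (in [0, 1]) of voxels where the deformation folds (det <= 0)."""
    return float(np.mean(jac.det <= 0.0))
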