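"""Synthetic brain-like phantoms and smooth, fold-free ground-truth deformations.

The generator emulates the atlas-to-subject registration setting: the moving
image is a labelled phantom built from strictly nested ellipsoidal shells
(cortex / white-matter / ventricle-like structures) with per-structure mean
intensities, Gaussian noise and optional smoothing; the fixed image is the
moving image resampled through a known smooth displacement field.  Because
the fixed image is constructed by warping, an exact ground truth exists for
every case, which anchors the package's recovery and evaluation tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (DisplacementField, LabelMap3D, Volume3D,
                       jacobian_determinant, warp_volume)


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one phantom.

    ``n_structures`` nested shells are rasterized from the outside in; label k
    overwrites label k-1 inside its ellipsoid, so labels 1..n are strictly
    nested and the background is 0.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    n_structures: int = 4
    intensities: tuple[float, ...] | None = None  # per structure; defaults to 1..n
    noise_sd: float = 0.05
    smooth_sd: float = 0.5

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_structures < 1:
            raise ValueError("need at least one structure")
        if self.intensities is None:
            self.intensities = tuple(float(k) / self.n_structures
                                     for k in range(1, self.n_structures + 1))
        if len(set(self.intensities)) != self.n_structures:
            raise ValueError("per-structure intensities must be distinct")


@dataclass
class FieldSpec:
    """Smooth random displacement: Gaussian-filtered white noise.

    ``amplitude`` is the maximum displacement magnitude in voxels after
    rescaling; ``smooth_sd`` the Gaussian smoothing in voxels.  Defaults keep
    the max spatial gradient well below 1, so fields are fold-free
    (verified voxel-exhaustively, with automatic amplitude back-off).
    """

    amplitude: float = 2.0
    smooth_sd: float = 4.0

    def __post_init__(self):
        if self.amplitude < 0 or self.smooth_sd <= 0:
            raise ValueError("amplitude must be >= 0 and smooth_sd > 0")


@dataclass
class RegistrationCase:
    """A (moving, fixed) pair with label maps and (optionally) the true field."""

    moving: Volume3D
    fixed: Volume3D
    moving_labels: LabelMap3D
    fixed_labels: LabelMap3D
    gt_field: DisplacementField | None = None
    seed: int | None = None


def make_phantom(spec: PhantomSpec, seed: int) -> tuple[Volume3D, LabelMap3D]:
    """Rasterize a nested-ellipsoid phantom; deterministic per seed."""
    rng = np.random.default_rng(seed)
    shape = np.array(spec.shape, dtype=np.float64)
    center = shape / 2.0 + rng.uniform(-0.05, 0.05, size=3) * shape
    # Outermost semi-axes leave a margin for deformation; shells shrink geometrically.
    outer = shape * rng.uniform(0.32, 0.38, size=3)
    if np.any(center - outer < 0) or np.any(center + outer > shape - 1):
        raise ValueError("ellipsoid exceeds the grid")
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in spec.shape], indexing="ij"))
    labels = np.zeros(spec.shape, dtype=np.int32)
    for k in range(1, spec.n_structures + 1):
        frac = 1.0 - (k - 1) / spec.n_structures * rng.uniform(0.85, 1.0)
        semi = outer * frac
        # random per-shell center jitter, kept inside the parent shell
        c = center + rng.uniform(-0.03, 0.03, size=3) * shape * (k > 1)
        r2 = sum(((grid[i] - c[i]) / semi[i]) ** 2 for i in range(3))
        mask = r2 <= 1.0
        if not mask.any():
            raise ValueError("empty structure: ellipsoid too small for the grid")
        labels[mask] = k
    intensity = np.zeros(spec.shape)
    for k in range(1, spec.n_structures + 1):
        intensity[labels == k] = spec.intensities[k - 1]
    if spec.smooth_sd > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.smooth_sd)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return Volume3D(intensity), LabelMap3D(labels)


def make_smooth_field(shape, spec: FieldSpec, seed: int,
                      max_retries: int = 10) -> DisplacementField:
    """Gaussian-smoothed white noise per component, rescaled to max |u| = amplitude.

    The resulting field is verified fold-free by an exhaustive Jacobian
    determinant scan; if folding is detected the amplitude is reduced by 20%
    and the field regenerated (bounded retries).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    noise = rng.standard_normal((3,) + shape)
    smooth = np.stack([ndimage.gaussian_filter(noise[i], spec.smooth_sd) for i in range(3)])
    amp = spec.amplitude
    if amp == 0:
        return DisplacementField(np.zeros((3,) + shape))
    mag = np.sqrt((smooth ** 2).sum(axis=0)).max()
    if mag == 0:
        return DisplacementField(np.zeros((3,) + shape))
    for _ in range(max_retries):
        fld = DisplacementField(smooth * (amp / mag))
        if jacobian_determinant(fld).det.min() > 0:
            return fld
        amp *= 0.8
    raise RuntimeError("could not generate a fold-free field within the retry budget")


def make_pair(phantom_spec: PhantomSpec, field_spec: FieldSpec, seed: int) -> RegistrationCase:
    """Moving = phantom; fixed = moving warped through a known smooth field."""
    vol, labels = make_phantom(phantom_spec, seed)
    fld = make_smooth_field(phantom_spec.shape, field_spec, seed + 1)
    fixed = warp_volume(vol, fld, mode="trilinear")
    fixed_labels = warp_volume(labels, fld, mode="nearest")
    return RegistrationCase(moving=vol, fixed=fixed, moving_labels=labels,
                            fixed_labels=fixed_labels, gt_field=fld, seed=seed)


def make_suite(n_cases: int, phantom_spec: PhantomSpec, field_spec: FieldSpec,
               seed: int) -> list[RegistrationCase]:
    """n seeded cases with per-case seeds derived from the suite seed."""
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s) % (2**31) for s in ss.generate_state(n_cases)]
    return [make_pair(phantom_spec, field_spec, s) for s in case_seeds]


def suite_digest(cases: list[RegistrationCase]) -> str:
    """SHA-256 over all case arrays; used for reproducibility checks."""
    h = hashlib.sha256()
    for c in cases:
        for arr in (c.moving.data, c.fixed.data, c.moving_labels.labels,
                    c.fixed_labels.labels):
            h.update(np.ascontiguousarray(arr).tobytes())
        if c.gt_field is not None:
            h.update(np.ascontiguousarray(c.gt_field.vectors).tobytes())
    return h.hexdigest()
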