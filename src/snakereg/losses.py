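"""Similarity losses, regularizers and evaluation metrics.

Every loss has a single implementation operating on autodiff tensors, so the
same code path serves three callers: metric evaluation (floats out), network
training, and the per-case field refinement loop.  Sums over windows follow
the local squared-correlation form; all volume-wide reductions are means, so
loss values are resolution independent.  The pseudo-ground-truth weight
``lambda_reg = 0.02`` balances field fidelity against smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import DisplacementField, LabelMap3D, Volume3D


@dataclass
class LossConfig:
    ncc_window: int = 9          # cubic local window n^3 for the correlation
    lambda_reg: float = 0.02     # weight of the smoothness term in the supervised loss
    energy_reg_weight: float = 1.0  # weight of the smoothness term in the refinement energy
    ssim_weight: float = 0.0     # optional SSIM hook in the refinement energy
    epsilon: float = 1e-5        # variance-product guard

    def __post_init__(self):
        if self.ncc_window < 3 or self.ncc_window % 2 == 0:
            raise ValueError("ncc_window must be odd and >= 3")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")


def _to_tensor(x) -> tuple[Tensor, bool]:
    """Coerce Volume3D / ndarray / Tensor to a Tensor; flag whether it was one."""
    if isinstance(x, Tensor):
        return x, True
    if isinstance(x, Volume3D):
        return Tensor(x.data), False
    if isinstance(x, DisplacementField):
        return Tensor(x.vectors), False
    return Tensor(np.asarray(x)), False


def _maybe_float(t: Tensor, any_tensor: bool):
    return t if any_tensor else float(t.data)


# ---------------------------------------------------------------------------
# local NCC

def _ncc_map(fixed: Tensor, warped: Tensor, window: int, eps: float) -> Tensor:
    """Per-voxel windowed squared correlation coefficient (zero-padded windows).

    Window statistics use a fixed count N = window^3 everywhere (the border
    windows see zero-padding), the standard box-sum decomposition.  Both
    images are first centered by their (detached) global means, which keeps
    the box sums small and the float32 cancellation error below 1e-6.
    """
    n3 = float(window ** 3)
    f = fixed - float(fixed.data.mean())
    w = warped - float(warped.data.mean())
    s_f = ad.box_sum(f, window)
    s_w = ad.box_sum(w, window)
    s_ff = ad.box_sum(ad.mul(f, f), window)
    s_ww = ad.box_sum(ad.mul(w, w), window)
    s_fw = ad.box_sum(ad.mul(f, w), window)
    u_f = ad.mul(s_f, 1.0 / n3)
    u_w = ad.mul(s_w, 1.0 / n3)
    cross = s_fw - ad.mul(u_w, s_f) - ad.mul(u_f, s_w) + ad.mul(ad.mul(u_f, u_w), n3)
    var_f = s_ff - ad.mul(ad.mul(u_f, s_f), 2.0) + ad.mul(ad.mul(u_f, u_f), n3)
    var_w = s_ww - ad.mul(ad.mul(u_w, s_w), 2.0) + ad.mul(ad.mul(u_w, u_w), n3)
    # clamp (not shift) the variance product: away from the guard the measure
    # is the exact correlation ratio, so perfectly aligned images sit at a
    # true zero-gradient optimum
    den = ad.maximum(ad.mul(var_f, var_w), Tensor(np.full(var_f.shape, eps, dtype=np.float32)))
    return ad.mul(ad.mul(cross, cross), ad.power(den, -1.0))


def local_ncc(fixed, warped, cfg: LossConfig | None = None, return_map: bool = False):
    """Mean local normalized cross-correlation (squared) in [0, 1].

    1.0 means perfect local linear dependence; the measure is symmetric and
    invariant to positive affine intensity maps of either argument.
    """
    cfg = cfg or LossConfig()
    f, ft = _to_tensor(fixed)
    w, wt = _to_tensor(warped)
    if f.shape != w.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {w.shape}")
    if min(f.shape) < cfg.ncc_window:
        raise ValueError(f"window {cfg.ncc_window} larger than volume {f.shape}")
    cc = _ncc_map(f, w, cfg.ncc_window, cfg.epsilon)
    if return_map:
        return cc.data if not (ft or wt) else cc
    out = ad.tmean(cc)
    if ft or wt:
        return out
    return float(np.clip(out.data, 0.0, 1.0))


# ---------------------------------------------------------------------------
# field smoothness

def grad_l2(fld, *_, **__):
    """Mean squared forward-difference gradient of the field, summed over the
    three displacement components and three spatial axes.

    A uniform translation scores exactly 0; a unit slope of one component
    along one axis scores 1.0 under the mean convention.
    """
    u, was_t = _to_tensor(fld)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError("expected a (3, D, H, W) displacement field")
    total = None
    for axis in range(1, 4):
        n = u.shape[axis]
        if n < 2:
            continue
        lead = [slice(None)] * 4
        lag = [slice(None)] * 4
        lead[axis] = slice(1, None)
        lag[axis] = slice(None, -1)
        d = u[tuple(lead)] - u[tuple(lag)]
        # mean over the (3, ...) diff array times 3 = sum over components of per-axis means
        term = ad.mul(ad.tmean(ad.mul(d, d)), 3.0)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("field must have at least one axis of length >= 2")
    return _maybe_float(total, was_t)


# ---------------------------------------------------------------------------
# differentiable warping and the refinement energy

_GRID_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _flat_grid(shape) -> np.ndarray:
    shape = tuple(shape)
    if shape not in _GRID_CACHE:
        axes = [np.arange(n, dtype=np.float32) for n in shape]
        _GRID_CACHE[shape] = np.stack(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T.copy()
    return _GRID_CACHE[shape]


def warp_image_t(moving, field: Tensor) -> Tensor:
    """Differentiable warp: resample ``moving`` at p + u(p), border-clamped.

    moving: Volume3D / ndarray (D, H, W) treated as constant; field: Tensor
    (3, D, H, W).  Returns a (D, H, W) Tensor; gradients flow into the field.
    """
    mov, _ = _to_tensor(moving)
    shape = mov.shape
    vol = ad.reshape(mov, (1,) + shape)
    coords = ad.add(ad.transpose(ad.reshape(field, (3, -1)), (1, 0)), _flat_grid(shape))
    out = ad.grid_sample(vol, coords)
    return ad.reshape(out, shape)


def energy(fixed, moving, field, cfg: LossConfig | None = None):
    """Refinement energy: (1 - local NCC(fixed, moving∘field)) + w_reg * grad_l2.

    The similarity term is written as a dissimilarity so a single minimizer
    applies; optionally a (1 - SSIM) term is added with ``ssim_weight``.
    """
    cfg = cfg or LossConfig()
    f, ft = _to_tensor(fixed)
    u, ut = _to_tensor(field)
    warped = warp_image_t(moving, u)
    e = ad.add(ad.mul(local_ncc(f, warped, cfg), -1.0), 1.0) + \
        ad.mul(grad_l2(u), cfg.energy_reg_weight)
    if cfg.ssim_weight > 0:
        e = e + ad.mul(ad.add(ad.mul(ssim3d(f, warped), -1.0), 1.0), cfg.ssim_weight)
    return _maybe_float(e, ft or ut)


def supervised_loss(field, pseudo, cfg: LossConfig | None = None):
    """Pseudo-ground-truth loss: mean (phi - phi_opt)^2 + lambda * grad_l2(phi).

    The mean runs over all voxel-components; ``pseudo`` is treated as a
    constant (no gradient flows into the refinement target).
    """
    cfg = cfg or LossConfig()
    u, ut = _to_tensor(field)
    p, _ = _to_tensor(pseudo)
    if u.shape != p.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {p.shape}")
    d = u - Tensor(p.data)  # detach the pseudo target
    out = ad.tmean(ad.mul(d, d)) + ad.mul(grad_l2(u), cfg.lambda_reg)
    return _maybe_float(out, ut)


# ---------------------------------------------------------------------------
# SSIM

def ssim3d(a, b, data_range: float = 1.0, sigma: float = 1.5,
           k1: float = 0.01, k2: float = 0.03):
    """Gaussian-windowed structural similarity, averaged over the volume."""
    x, xt = _to_tensor(a)
    y, yt = _to_tensor(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_x = ad.gaussian_blur(x, sigma)
    mu_y = ad.gaussian_blur(y, sigma)
    xx = ad.gaussian_blur(ad.mul(x, x), sigma)
    yy = ad.gaussian_blur(ad.mul(y, y), sigma)
    xy = ad.gaussian_blur(ad.mul(x, y), sigma)
    vx = xx - ad.mul(mu_x, mu_x)
    vy = yy - ad.mul(mu_y, mu_y)
    cxy = xy - ad.mul(mu_x, mu_y)
    num = ad.mul(ad.add(ad.mul(ad.mul(mu_x, mu_y), 2.0), c1),
                 ad.add(ad.mul(cxy, 2.0), c2))
    den = ad.mul(ad.add(ad.mul(mu_x, mu_x) + ad.mul(mu_y, mu_y), c1),
                 ad.add(vx + vy, c2))
    out = ad.tmean(ad.mul(num, ad.power(den, -1.0)))
    return _maybe_float(out, xt or yt)


# ---------------------------------------------------------------------------
# Dice

def dice(a: LabelMap3D, b: LabelMap3D) -> tuple[dict[int, float], float]:
    """Per-label Dice overlap 2|A∩B| / (|A|+|B|) and its mean over labels
    present in either map; background (0) is excluded."""
    la, lb = a.labels, b.labels
    if la.shape != lb.shape:
        raise ValueError(f"shape mismatch: {la.shape} vs {lb.shape}")
    labels = sorted(set(np.unique(la)) | set(np.unique(lb)))
    labels = [int(l) for l in labels if l != 0]
    if not labels:
        raise ValueError("no foreground labels in either map")
    per: dict[int, float] = {}
    for lab in labels:
        ma, mb = la == lab, lb == lab
        denom = int(ma.sum()) + int(mb.sum())
        per[lab] = 2.0 * int((ma & mb).sum()) / denom if denom else 0.0
    return per, float(np.mean(list(per.values())))
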