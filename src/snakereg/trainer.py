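"""Instance optimization and the weakly supervised training loop.

The two-stage scheme: the network predicts a field phi; an Adam loop then
refines a *detached copy* of phi against the image-matching energy
(1 - local NCC + smoothness) for ``iterations`` steps (n = 10 by default,
learning rate 0.1), yielding phi_opt.  phi_opt serves as a pseudo ground
truth: the network is updated by one Adam step (lr 1e-4) on
``mean (phi - phi_opt)^2 + lambda * grad_l2(phi)``.  Because phi is detached
before refinement, no gradient ever flows from the pseudo label back into
the network — supervision is purely through the regression target, and the
loop bootstraps: better predictions give the refiner a better start, which
gives stronger supervision.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import (DisplacementField, LabelMap3D, Volume3D,
                       jacobian_determinant, pct_nondiffeomorphic, warp_volume)
from .losses import (LossConfig, dice, energy, grad_l2, local_ncc,
                     supervised_loss, warp_image_t)
from .network import STUNetPlus
from .nn import Adam, Parameter
from .synthetic import RegistrationCase


@dataclass
class OptStageConfig:
    """Per-case field refinement: n Adam iterations at lr 0.1."""

    iterations: int = 10
    lr: float = 0.1
    betas: tuple[float, float] = (0.9, 0.999)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.iterations < 0 or self.lr <= 0:
            raise ValueError("iterations must be >= 0 and lr > 0")


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 1          # cases per optimizer step
    net_lr: float = 1e-4
    seed: int = 0
    augment: bool = True
    oss: bool = True             # pseudo-ground-truth supervision on/off
    gate_threshold: float = 0.0  # accept phi_opt only if it improves the energy by this fraction
    val_fraction: float = 0.2
    val_every: int = 5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def instance_optimize(moving, fixed, init_field: DisplacementField,
                      cfg: OptStageConfig | None = None) -> DisplacementField:
    """Refine a displacement field by Adam on the matching energy.

    Pure function of its inputs: the initial field is copied, never mutated.
    Raises on a non-finite energy (diverging refinement).
    """
    cfg = cfg or OptStageConfig()
    mov = moving if isinstance(moving, Volume3D) else Volume3D(np.asarray(moving))
    fix = fixed if isinstance(fixed, Volume3D) else Volume3D(np.asarray(fixed))
    if mov.shape != init_field.shape:
        raise ValueError("field shape does not match the images")
    param = Parameter(init_field.vectors)
    opt = Adam([param], lr=cfg.lr, betas=cfg.betas)
    for it in range(cfg.iterations):
        e = energy(fix, mov, param, cfg.loss)
        if not np.isfinite(e.data):
            raise RuntimeError(f"non-finite energy at refinement iteration {it}")
        opt.zero_grad()
        e.backward()
        # converged fields produce pure rounding-noise gradients, which Adam
        # would amplify to full-size steps; stop instead of random-walking
        if np.abs(param.grad).max() < 1e-6:
            break
        opt.step()
    return DisplacementField(param.data.astype(np.float64))


def _unsupervised_loss(phi: Tensor, case: RegistrationCase, cfg: LossConfig) -> Tensor:
    warped = warp_image_t(case.moving, phi)
    sim = ad.add(ad.mul(local_ncc(Tensor(case.fixed.data), warped, cfg), -1.0), 1.0)
    return sim + ad.mul(grad_l2(phi), cfg.lambda_reg)


def train_step(case: RegistrationCase, net: STUNetPlus, opt: Adam,
               opt_cfg: OptStageConfig, loss_cfg: LossConfig,
               oss: bool = True, gate_threshold: float = 0.0,
               accumulate: bool = False) -> dict:
    """One weakly supervised step on one case; returns the logged scalars.

    With ``accumulate`` the gradient is added but no optimizer step is taken
    (mini-batch accumulation); the caller steps and zeroes.
    """
    pair = Tensor(np.stack([case.moving.data, case.fixed.data]))
    phi = net.field_tensor(pair)
    log: dict[str, float] = {}
    if oss:
        phi_init = DisplacementField(phi.data.astype(np.float64))
        phi_opt = instance_optimize(case.moving, case.fixed, phi_init, opt_cfg)
        e_before = energy(case.fixed, case.moving, phi_init, opt_cfg.loss)
        e_after = energy(case.fixed, case.moving, phi_opt, opt_cfg.loss)
        accepted = e_after <= e_before - gate_threshold * abs(e_before)
        if not accepted:  # low-confidence pseudo label: fall back to self-supervision
            phi_opt = phi_init
        loss = supervised_loss(phi, phi_opt, loss_cfg)
        with ad.no_grad():
            mse = float(np.mean((phi.data - phi_opt.vectors.astype(np.float32)) ** 2))
            reg = grad_l2(phi_init)
        log.update(energy_before=float(e_before), energy_after=float(e_after),
                   pseudo_accepted=float(accepted), mse=mse, reg=float(reg))
    else:
        loss = _unsupervised_loss(phi, case, loss_cfg)
    lval = float(loss.data)
    log["loss"] = lval
    if not np.isfinite(lval):
        log["skipped"] = 1.0
        return log
    loss.backward()
    if not accumulate:
        opt.step()
        opt.zero_grad()
    return log


_FLIPS = [(), (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]


def _augment(case: RegistrationCase, rng: np.random.Generator) -> RegistrationCase:
    """Label-safe augmentation: a random axis permutation (90-degree
    rotations, cubic grids) plus random flips, applied jointly to both
    images and label maps.  The ground-truth field is dropped (its vectors
    would need reorientation and training never uses it)."""
    d, h, w = case.moving.shape
    perm = tuple(rng.permutation(3)) if d == h == w else (0, 1, 2)
    flips = _FLIPS[rng.integers(len(_FLIPS))]

    def tf(arr):
        out = np.transpose(arr, perm)
        return np.flip(out, flips).copy() if flips else out.copy()

    return RegistrationCase(
        moving=Volume3D(tf(case.moving.data)), fixed=Volume3D(tf(case.fixed.data)),
        moving_labels=LabelMap3D(tf(case.moving_labels.labels)),
        fixed_labels=LabelMap3D(tf(case.fixed_labels.labels)),
        gt_field=None, seed=case.seed)


def train(cases: list[RegistrationCase], net: STUNetPlus,
          train_cfg: TrainConfig | None = None,
          opt_cfg: OptStageConfig | None = None,
          loss_cfg: LossConfig | None = None,
          val_cases: list[RegistrationCase] | None = None) -> dict:
    """Epoch loop with augmentation, periodic validation and best-state retention.

    Returns a history dict; the best-validation parameters are kept under
    ``"best_state"`` (and are loaded back into ``net`` on exit).
    """
    if not cases:
        raise ValueError("training set is empty")
    tc = train_cfg or TrainConfig()
    oc = opt_cfg or OptStageConfig()
    lc = loss_cfg or LossConfig()
    rng = np.random.default_rng(tc.seed)
    if val_cases is None:
        n_val = max(1, int(round(tc.val_fraction * len(cases)))) if len(cases) > 1 else 0
        val_cases = cases[len(cases) - n_val:]
        cases = cases[:len(cases) - n_val] or cases
    opt = Adam(net.parameters(), lr=tc.net_lr)
    history: dict = {"steps": [], "val": [], "seed": tc.seed}
    best = {"dice": -1.0, "state": net.state_dict(), "epoch": -1}

    def validate(epoch):
        rep = evaluate(net, val_cases)
        history["val"].append({"epoch": epoch, **{k: rep[k] for k in
                                                  ("mean_dice", "sd_dice", "pct_folding")}})
        if rep["mean_dice"] > best["dice"]:
            best.update(dice=rep["mean_dice"], state=net.state_dict(), epoch=epoch)
        return rep

    if val_cases:
        validate(-1)  # identity-start baseline
    for epoch in range(tc.epochs):
        order = rng.permutation(len(cases))
        for j, ci in enumerate(order):
            case = cases[ci]
            if tc.augment:
                case = _augment(case, rng)
            accumulate = tc.batch_size > 1 and (j + 1) % tc.batch_size != 0
            log = train_step(case, net, opt, oc, lc, oss=tc.oss,
                             gate_threshold=tc.gate_threshold, accumulate=accumulate)
            history["steps"].append({"epoch": epoch, "case": int(ci), **log})
        if val_cases and ((epoch + 1) % tc.val_every == 0 or epoch == tc.epochs - 1):
            validate(epoch)
    if val_cases and best["epoch"] >= -1:
        net.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_dice"] = best["dice"]
    history["best_state"] = best["state"]
    return history


def evaluate(net_or_fields, cases: list[RegistrationCase]) -> dict:
    """Dice / folding / runtime report over labelled cases.

    ``net_or_fields`` is a network, a single field, or one field per case.
    Label maps are warped in nearest mode; folding is reported as the
    percentage of voxels with Jacobian determinant <= 0.
    """
    if isinstance(net_or_fields, DisplacementField):
        fields = [net_or_fields] * len(cases)
    elif isinstance(net_or_fields, (list, tuple)):
        fields = list(net_or_fields)
    else:
        fields = None
    per_case = []
    skipped = 0
    for i, case in enumerate(cases):
        if case.moving_labels is None or case.fixed_labels is None:
            skipped += 1
            continue
        t0 = time.perf_counter()
        if fields is None:
            fld = net_or_fields.forward(case.moving, case.fixed).field
        else:
            fld = fields[i]
        warped_labels = warp_volume(case.moving_labels, fld, mode="nearest")
        _, mean_d = dice(warped_labels, case.fixed_labels)
        pct = 100.0 * pct_nondiffeomorphic(jacobian_determinant(fld))
        per_case.append({"case": i, "dice": mean_d, "pct_folding": pct,
                         "runtime_s": time.perf_counter() - t0})
    if not per_case:
        raise ValueError("no labelled cases to evaluate")
    dices = np.array([c["dice"] for c in per_case])
    pcts = np.array([c["pct_folding"] for c in per_case])
    return {"mean_dice": float(dices.mean()), "sd_dice": float(dices.std()),
            "pct_folding": float(pcts.mean()), "sd_pct_folding": float(pcts.std()),
            "runtime_s": float(np.sum([c["runtime_s"] for c in per_case])),
            "n_cases": len(per_case), "n_skipped": skipped, "per_case": per_case}
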