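"""NIfTI readers/writers, the YAML run configuration, and run manifests.

Volumes and label maps are 3-D NIfTI-1 images (.nii or .nii.gz).
Displacement fields are 4-D NIfTI with the vector dimension last and
component order (du_d, du_h, du_w) in voxel units, recorded in the header
``descrip`` field.  Affine headers are stored and round-tripped but never
used for resampling — all geometry is voxel-indexed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import DisplacementField, LabelMap3D, Volume3D
from .losses import LossConfig
from .network import NetworkConfig
from .snake import SnakeKernelSpec
from .swin import SwinConfig
from .trainer import OptStageConfig, TrainConfig

log = logging.getLogger("snakereg")

FIELD_TAG = "disp(d,h,w) voxel"


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got rank {data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(np.asarray(data, dtype=np.float64), spacing=tuple(float(z) for z in zooms))


def write_volume(vol: Volume3D, path):
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def read_label_map(path) -> LabelMap3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label map, got rank {data.ndim}")
    return LabelMap3D(np.asarray(np.rint(data), dtype=np.int32))


def write_label_map(labels: LabelMap3D, path):
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), np.eye(4)), str(path))


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (D, H, W, 3) field, got shape {data.shape}")
    descrip = img.header["descrip"].item().decode(errors="replace")
    if FIELD_TAG not in descrip:
        warnings.warn(f"{path}: component-order tag missing from header; "
                      f"assuming the default {FIELD_TAG!r}")
    return DisplacementField(np.moveaxis(np.asarray(data, dtype=np.float64), -1, 0))


def write_field(fld: DisplacementField, path):
    img = nib.Nifti1Image(np.moveaxis(fld.vectors, 0, -1).astype(np.float32), np.eye(4))
    img.header["descrip"] = FIELD_TAG.encode()
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# run configuration

def _strict_dataclass(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs, loadable from one YAML document."""

    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    opt_stage: OptStageConfig = dataclasses.field(default_factory=OptStageConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    data_dir: str | None = None
    out_dir: str = "runs"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"network", "loss", "opt_stage", "train", "data_dir", "out_dir", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        net_raw = dict(raw.get("network", {}))
        swin = _strict_dataclass(SwinConfig, net_raw.pop("swin", {}), "network.swin")
        snake = _strict_dataclass(SnakeKernelSpec, net_raw.pop("snake", {}), "network.snake")
        network = _strict_dataclass(
            NetworkConfig, {"swin": swin, "snake": snake, **net_raw}, "network")
        opt_raw = dict(raw.get("opt_stage", {}))
        opt_loss = _strict_dataclass(LossConfig, opt_raw.pop("loss", {}), "opt_stage.loss")
        return cls(
            network=network,
            loss=_strict_dataclass(LossConfig, raw.get("loss", {}), "loss"),
            opt_stage=_strict_dataclass(OptStageConfig, {"loss": opt_loss, **opt_raw}, "opt_stage"),
            train=_strict_dataclass(TrainConfig, raw.get("train", {}), "train"),
            data_dir=raw.get("data_dir"),
            out_dir=raw.get("out_dir", "runs"),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "loss": dataclasses.asdict(self.loss),
            "opt_stage": dataclasses.asdict(self.opt_stage),
            "train": dataclasses.asdict(self.train),
            "data_dir": self.data_dir, "out_dir": self.out_dir, "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# case archives (simulate output / train & evaluate input)

def save_case(case, directory, index: int):
    from .synthetic import RegistrationCase  # noqa: F401  (type only)

    d = Path(directory)
    stem = f"case_{index:03d}"
    write_volume(case.moving, d / f"{stem}_moving.nii.gz")
    write_volume(case.fixed, d / f"{stem}_fixed.nii.gz")
    write_label_map(case.moving_labels, d / f"{stem}_moving_labels.nii.gz")
    write_label_map(case.fixed_labels, d / f"{stem}_fixed_labels.nii.gz")
    if case.gt_field is not None:
        write_field(case.gt_field, d / f"{stem}_gt_field.nii.gz")


def load_case(directory, index: int):
    from .synthetic import RegistrationCase

    d = Path(directory)
    stem = f"case_{index:03d}"
    gt = d / f"{stem}_gt_field.nii.gz"
    return RegistrationCase(
        moving=read_volume(d / f"{stem}_moving.nii.gz"),
        fixed=read_volume(d / f"{stem}_fixed.nii.gz"),
        moving_labels=read_label_map(d / f"{stem}_moving_labels.nii.gz"),
        fixed_labels=read_label_map(d / f"{stem}_fixed_labels.nii.gz"),
        gt_field=read_field(gt) if gt.exists() else None,
    )


def load_suite_dir(directory):
    d = Path(directory)
    indices = sorted(int(p.name.split("_")[1]) for p in d.glob("case_*_moving.nii.gz"))
    return [load_case(d, i) for i in indices]


def write_manifest(path, cfg: RunConfig | None, seed: int, extra: dict | None = None):
    """Record everything needed to reproduce a run's artifacts."""
    import scipy

    manifest = {
        "seed": seed,
        "config": cfg.to_dict() if cfg else None,
        "config_digest": cfg.digest() if cfg else None,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "nibabel": nib.__version__},
    }
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
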