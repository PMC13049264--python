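"""HDF5 dataset container, NIfTI / CSV export, and YAML configuration.

The container keeps everything one acquisition needs in a single HDF5 file:

* ``/kspace`` — complex (frames, coils, n_y, n_x), the zero-filled data;
* ``/mask`` — uint8 (frames, n_y, n_x) sampling masks;
* ``/csm`` — complex (coils, n_y, n_x) coil sensitivity maps (optional);
* ``/motion_gt`` — float (frames, 3) ground-truth (theta1 rad, theta2 px,
  theta3 px) (optional);
* root attributes — acquisition metadata (FOV, resolution, TR/TE/TS, sampling
  scheme, seed) plus a schema version.

Complex data are stored with h5py's native compound (r, i) float64 pairs.
Round trips are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kspace import RigidParams

__all__ = [
    "SCHEMA_VERSION",
    "Container",
    "write_container",
    "read_container",
    "export_nifti",
    "read_nifti_series",
    "export_params_csv",
    "read_params_csv",
    "load_config",
]

SCHEMA_VERSION = 1


@dataclass
class Container:
    """In-memory mirror of the HDF5 dataset container."""

    kspace: np.ndarray  # (frames, coils, n_y, n_x) complex
    mask: np.ndarray  # (frames, n_y, n_x) uint8
    csm: np.ndarray | None = None  # (coils, n_y, n_x) complex
    motion_gt: np.ndarray | None = None  # (frames, 3)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kspace = np.asarray(self.kspace, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.kspace.ndim != 4:
            raise ValueError("kspace must be (frames, coils, n_y, n_x)")
        if self.mask.shape != (self.kspace.shape[0],) + self.kspace.shape[2:]:
            raise ValueError(
                f"mask shape {self.mask.shape} inconsistent with kspace {self.kspace.shape}"
            )
        if self.csm is not None:
            self.csm = np.asarray(self.csm, dtype=complex)
            if self.csm.shape != self.kspace.shape[1:]:
                raise ValueError("csm shape inconsistent with kspace")
        if self.motion_gt is not None:
            self.motion_gt = np.asarray(self.motion_gt, dtype=float)
            if self.motion_gt.shape != (self.kspace.shape[0], 3):
                raise ValueError("motion_gt must be (frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.kspace.shape[0]


def write_container(container: Container, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["complex_convention"] = "h5py compound (r, i) float64"
        for key, val in container.meta.items():
            fh.attrs[key] = val
        fh.create_dataset("kspace", data=container.kspace)
        fh.create_dataset("mask", data=container.mask.astype(np.uint8))
        if container.csm is not None:
            fh.create_dataset("csm", data=container.csm)
        if container.motion_gt is not None:
            fh.create_dataset("motion_gt", data=container.motion_gt)


def read_container(path: str | Path) -> Container:
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unknown schema version {version} in {path}; expected {SCHEMA_VERSION}"
            )
        if "kspace" not in fh:
            raise KeyError(f"container {path} lacks the mandatory /kspace dataset")
        if "mask" not in fh:
            raise KeyError(f"container {path} lacks the mandatory /mask dataset")
        kspace = fh["kspace"][()]
        mask = fh["mask"][()]
        csm = fh["csm"][()] if "csm" in fh else None
        motion = fh["motion_gt"][()] if "motion_gt" in fh else None
        meta = {
            k: v for k, v in fh.attrs.items()
            if k not in ("schema_version", "complex_convention")
        }
    return Container(kspace=kspace, mask=mask, csm=csm, motion_gt=motion, meta=meta)


def export_nifti(series: np.ndarray, path: str | Path, resolution_mm: float = 1.0) -> None:
    """Write a dynamic magnitude series (frames, n_y, n_x) as NIfTI-1.

    Stored as (n_y, n_x, 1, frames) with in-plane pixel spacing from the
    metadata."""
    series = np.abs(np.asarray(series))
    if series.ndim == 2:
        series = series[None]
    data = np.transpose(series, (1, 2, 0))[:, :, None, :].astype(np.float64)
    affine = np.diag([resolution_mm, resolution_mm, 1.0, 1.0])
    try:
        nib.save(nib.Nifti1Image(data, affine), str(path))
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed to write NIfTI to {path}: {exc}") from exc


def read_nifti_series(path: str | Path) -> np.ndarray:
    """Inverse of :func:`export_nifti`: returns (frames, n_y, n_x)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return np.transpose(data[:, :, 0, :], (2, 0, 1))


def export_params_csv(
    params: Sequence[RigidParams],
    path: str | Path,
    abs_v: Sequence[float] | None = None,
) -> None:
    """Plain-text table: frame, theta1_rad, theta2_px, theta3_px, abs_V."""
    rows = {
        "frame": np.arange(len(params)),
        "theta1_rad": [p.theta1 for p in params],
        "theta2_px": [p.theta2 for p in params],
        "theta3_px": [p.theta3 for p in params],
        "abs_V": list(abs_v) if abs_v is not None else [np.nan] * len(params),
    }
    try:
        pd.DataFrame(rows).to_csv(path, index=False)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed to write parameter CSV to {path}: {exc}") from exc


def read_params_csv(path: str | Path) -> list[RigidParams]:
    df = pd.read_csv(path)
    return [
        RigidParams(r.theta1_rad, r.theta2_px, r.theta3_px) for r in df.itertuples()
    ]


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON configuration file into a flat dict (empty if None)."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
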