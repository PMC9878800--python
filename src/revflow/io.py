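"""Dataset container and NIfTI/JSON on-disk layout.

A 4D flow dataset is stored as three 4D NIfTI volumes (one per velocity
component, mm/s, float32), one 4D magnitude volume, one 3D binary aorta
mask, and a JSON sidecar with the acquisition metadata (voxel spacing,
temporal resolution, venc).  World coordinates follow the voxel-center
convention: voxel ``(i, j, k)`` sits at ``(i*sx, j*sy, k*sz)`` mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError

SIDECAR_NAME = "flow.json"


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity field on a regular grid.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz, nt, 3)`` in mm/s; the last axis
        holds the (x, y, z) velocity components.
    spacing_mm
        Voxel spacing along the three spatial axes.
    dt_ms
        Temporal resolution of one cardiac frame.
    venc_cms
        Velocity-encoding limit in cm/s.  Velocities with magnitude above
        venc wrap by multiples of ``2*venc`` at acquisition time; values
        may legitimately exceed venc after antialiasing.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    dt_ms: float
    venc_cms: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ConfigurationError(
                f"velocity values must have shape (nx, ny, nz, nt, 3), got {self.values.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("voxel spacing must be strictly positive")
        if self.dt_ms <= 0:
            raise ConfigurationError("temporal resolution dt_ms must be strictly positive")
        if self.venc_cms <= 0:
            raise ConfigurationError("venc must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("velocity field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def venc_mms(self) -> float:
        """Encoding limit in mm/s (the unit of the stored values)."""
        return self.venc_cms * 10.0

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(self.values.copy(), self.spacing_mm, self.dt_ms, self.venc_cms)


@dataclass
class FlowDataset:
    """A velocity field plus the co-registered magnitude series and aorta mask."""

    velocity: VelocityField4D
    magnitude: np.ndarray  # (nx, ny, nz, nt)
    mask: np.ndarray  # (nx, ny, nz) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.magnitude.shape != self.velocity.values.shape[:4]:
            raise ConfigurationError("magnitude shape does not match the velocity grid")
        if self.mask.shape != self.velocity.grid_shape:
            raise ConfigurationError("mask shape does not match the velocity grid")


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def save_dataset(out_dir: str | Path, dataset: FlowDataset) -> Path:
    """Write a dataset as NIfTI volumes plus a JSON sidecar; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(dataset.velocity.spacing_mm)
    for axis, name in enumerate(("vel_x", "vel_y", "vel_z")):
        img = nib.Nifti1Image(dataset.velocity.values[..., axis].astype(np.float32), aff)
        nib.save(img, out / f"{name}.nii")
    nib.save(nib.Nifti1Image(dataset.magnitude.astype(np.float32), aff), out / "mag.nii")
    nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), aff), out / "mask.nii")
    sidecar = {
        "spacing_mm": list(dataset.velocity.spacing_mm),
        "dt_ms": dataset.velocity.dt_ms,
        "venc_cms": dataset.velocity.venc_cms,
        **dataset.meta,
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out


def load_dataset(in_dir: str | Path) -> FlowDataset:
    """Read a dataset previously written by :func:`save_dataset`."""
    src = Path(in_dir)
    sidecar = json.loads((src / SIDECAR_NAME).read_text())
    comps = [np.asanyarray(nib.load(src / f"vel_{c}.nii").dataobj, dtype=np.float32) for c in "xyz"]
    values = np.stack(comps, axis=-1)
    magnitude = np.asanyarray(nib.load(src / "mag.nii").dataobj, dtype=np.float32)
    mask = np.asanyarray(nib.load(src / "mask.nii").dataobj) > 0
    velocity = VelocityField4D(
        values,
        tuple(sidecar["spacing_mm"]),
        float(sidecar["dt_ms"]),
        float(sidecar["venc_cms"]),
    )
    meta = {k: v for k, v in sidecar.items() if k not in ("spacing_mm", "dt_ms", "venc_cms")}
    return FlowDataset(velocity, magnitude, mask, meta)
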