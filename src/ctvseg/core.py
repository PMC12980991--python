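"""Domain types for gridded CT volumes and masks, with NIfTI I/O.

Axis convention: the first array axis is the slice (superior-inferior)
axis, so voxel grids are ordered (slice, row, column) and spacing is
``(dz, dy, dx)`` in millimetres.  Volumes are reoriented to the closest
canonical anatomical orientation at load; oblique grids are not
supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "BinaryMask", "MultiPhaseCase",
           "read_volume", "read_mask", "write_volume"]


def _check_spacing(spacing):
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or not all(np.isfinite(s) and s > 0 for s in sp):
        raise ValueError(f"spacing must be three positive finite numbers, got {spacing}")
    return sp


@dataclass
class ImageVolume:
    """One CT phase: a 3-D scalar grid (HU) with physical spacing."""

    voxels: np.ndarray
    spacing: tuple
    phase: str = "N"  # "N" (non-contrast) or "C" (contrast-enhanced)
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D image, got {self.voxels.ndim}D")
        if not np.isfinite(self.voxels).all():
            raise ValueError("image contains non-finite voxel values")
        self.spacing = _check_spacing(self.spacing)
        if self.phase not in ("N", "C"):
            raise ValueError(f"phase must be 'N' or 'C', got {self.phase!r}")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class BinaryMask:
    """A {0,1} grid aligned to a volume (ground truth or prediction)."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected 3D mask, got {v.ndim}D")
        vals = np.unique(v)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must contain only 0/1, found values {vals[:5]}")
        self.voxels = v.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self):
        return self.voxels.shape

    def volume_cm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing)) / 1000.0


@dataclass
class MultiPhaseCase:
    """Paired same-grid phases plus, when supervised, the target mask."""

    case_id: str
    nect: ImageVolume
    cect: ImageVolume
    ctv: Optional[BinaryMask] = None

    def __post_init__(self):
        grids = [self.nect, self.cect] + ([self.ctv] if self.ctv is not None else [])
        shapes = {g.shape for g in grids}
        spacings = {tuple(np.round(g.spacing, 6)) for g in grids}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError(
                f"phases and mask must share shape and spacing, got shapes "
                f"{shapes} spacings {spacings}")

    @property
    def shape(self):
        return self.nect.shape

    @property
    def spacing(self):
        return self.nect.spacing


def _load_canonical(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D in {path}")
    # nibabel arrays are (x, y, z); transpose to (slice, row, column)
    data = np.ascontiguousarray(data.T)
    dx, dy, dz = img.header.get_zooms()[:3]
    return data, (float(dz), float(dy), float(dx))


def read_volume(path, phase: str = "N", case_id: str = "") -> ImageVolume:
    """Read a 3-D NIfTI image as an ImageVolume (axis order slice,row,col)."""
    data, spacing = _load_canonical(path)
    return ImageVolume(voxels=data.astype(np.float32), spacing=spacing,
                       phase=phase, case_id=case_id)


def read_mask(path) -> BinaryMask:
    """Read a 3-D NIfTI label image as a BinaryMask (values binarized >0.5)."""
    data, spacing = _load_canonical(path)
    return BinaryMask(voxels=(data > 0.5).astype(np.uint8), spacing=spacing)


def write_volume(v, path) -> None:
    """Write an ImageVolume or BinaryMask to NIfTI.

    Voxels and spacing survive a read round-trip bit-for-bit (masks are
    stored as unsigned 8-bit integers, images as float32).
    """
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    voxels = np.asarray(v.voxels)
    dz, dy, dx = v.spacing
    if isinstance(v, BinaryMask) or voxels.dtype.kind in "ui":
        data = voxels.astype(np.uint8)
    else:
        data = voxels.astype(np.float32)
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data.T, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
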