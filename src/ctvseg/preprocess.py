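"""Preprocessing and augmentation chain.

The pipeline mirrors the common CT scheme: intensities are truncated to
the 0.5th/99.5th percentiles of the pooled training-set distribution,
z-scored with training-set statistics computed on the clipped range,
volumes are resampled to a common (5, 1, 1) mm grid, and training
samples are randomly flipped, rotated within +/-15 degrees about each
axis, and cropped or padded to a fixed patch size.  All geometric
operations apply one shared transform to every grid of a case; the mask
is always interpolated nearest-neighbour and re-binarized.

Intensity statistics are computed once from the training set, persisted
as a small key-value text file next to checkpoints, and reused at
inference so that prediction never depends on test-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, MultiPhaseCase

__all__ = [
    "PreprocessConfig",
    "IntensityStats",
    "clip_and_normalize",
    "resample",
    "augment",
    "crop_or_pad",
    "compute_window",
    "apply_window",
    "undo_window",
]


@dataclass(frozen=True)
class PreprocessConfig:
    clip_lo_pct: float = 0.5
    clip_hi_pct: float = 99.5
    target_spacing: Tuple[float, float, float] = (5.0, 1.0, 1.0)
    patch_size: Tuple[int, int, int] = (40, 224, 192)
    flip_prob_per_axis: float = 0.5
    rot_range_deg: Tuple[float, float] = (-15.0, 15.0)

    def __post_init__(self):
        if not (0 <= self.clip_lo_pct < self.clip_hi_pct <= 100):
            raise ValueError("need 0 <= clip_lo_pct < clip_hi_pct <= 100")
        if any(int(p) <= 0 or p != int(p) for p in self.patch_size):
            raise ValueError("patch_size components must be positive integers")
        if not 0 <= self.flip_prob_per_axis <= 1:
            raise ValueError("flip probability must be in [0, 1]")


@dataclass(frozen=True)
class IntensityStats:
    """Clip bounds and first two moments of the clipped training intensities."""

    lo: float
    hi: float
    mean: float
    std: float

    @classmethod
    def from_volumes(cls, volumes: Sequence[ImageVolume],
                     clip_lo_pct: float = 0.5,
                     clip_hi_pct: float = 99.5) -> "IntensityStats":
        pooled = np.concatenate([np.asarray(v.voxels).ravel() for v in volumes])
        lo, hi = np.percentile(pooled, [clip_lo_pct, clip_hi_pct])
        clipped = np.clip(pooled, lo, hi)
        return cls(lo=float(lo), hi=float(hi),
                   mean=float(clipped.mean()), std=float(clipped.std()))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k in ("lo", "hi", "mean", "std"):
                fh.write(f"{k} = {getattr(self, k)!r}\n")

    @classmethod
    def load(cls, path) -> "IntensityStats":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.split("=", 1)
                    kv[k.strip()] = float(v)
        return cls(**kv)


def clip_and_normalize(v: ImageVolume, stats: IntensityStats) -> ImageVolume:
    """Truncate to [lo, hi] then z-score with the training statistics."""
    if stats.std == 0:
        raise ValueError("degenerate intensity distribution (std == 0)")
    out = (np.clip(v.voxels.astype(np.float64), stats.lo, stats.hi)
           - stats.mean) / stats.std
    return ImageVolume(voxels=out.astype(np.float32), spacing=v.spacing,
                       phase=v.phase, case_id=v.case_id)


def resample(v, target_spacing):
    """Resample to a new voxel spacing.

    Output shape per axis is ``round(shape * spacing / target)``; images
    are interpolated linearly, masks nearest-neighbour (so the output
    stays binary).
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    factors = tuple(s / t for s, t in zip(v.spacing, target))
    out_shape = tuple(int(round(n * f)) for n, f in zip(v.voxels.shape, factors))
    if any(n == 0 for n in out_shape):
        raise ValueError(f"resampling to {target} collapses shape to {out_shape}")
    if np.allclose(factors, 1.0):
        return _replace_voxels(v, v.voxels.copy(), target)
    if isinstance(v, BinaryMask):
        data = ndimage.zoom(v.voxels, factors, order=0, mode="nearest",
                            grid_mode=False)
        data = (data > 0.5).astype(np.uint8)
    else:
        data = ndimage.zoom(v.voxels.astype(np.float32), factors, order=1,
                            mode="nearest")
    assert data.shape == out_shape, (data.shape, out_shape)
    return _replace_voxels(v, data, target)


def _replace_voxels(v, data, spacing):
    if isinstance(v, BinaryMask):
        return BinaryMask(voxels=data, spacing=spacing)
    return ImageVolume(voxels=data, spacing=spacing, phase=v.phase,
                       case_id=v.case_id)


_ROT_PLANES = ((1, 2), (0, 2), (0, 1))  # about z, then y, then x


def _transform_grid(data, flips, angles, order, cval):
    out = data
    for ax, f in enumerate(flips):
        if f:
            out = np.flip(out, axis=ax)
    for plane, ang in zip(_ROT_PLANES, angles):
        if ang != 0.0:
            out = ndimage.rotate(out, ang, axes=plane, reshape=False,
                                 order=order, mode="constant", cval=cval)
    return np.ascontiguousarray(out)


def augment(case: MultiPhaseCase, seed: int,
            flip_prob: float = 0.5,
            rot_range_deg: Tuple[float, float] = (-15.0, 15.0)) -> MultiPhaseCase:
    """Random flips and rotations, identical across all grids of the case.

    Flip decisions are drawn per axis with probability ``flip_prob``;
    rotation angles are drawn independently and uniformly from
    ``rot_range_deg`` about the z, y and x axes (applied in that order,
    about the grid centre).  Images interpolate linearly, the mask
    nearest-neighbour with re-binarization.  Fully determined by seed.
    """
    rng = np.random.default_rng(seed)
    flips = rng.random(3) < flip_prob
    lo, hi = rot_range_deg
    angles = rng.uniform(lo, hi, size=3) if hi > lo else np.zeros(3)

    def img(v):
        data = _transform_grid(v.voxels.astype(np.float32), flips, angles,
                               order=1, cval=float(v.voxels.min()))
        return ImageVolume(voxels=data, spacing=v.spacing, phase=v.phase,
                           case_id=v.case_id)

    ctv = None
    if case.ctv is not None:
        m = _transform_grid(case.ctv.voxels, flips, angles, order=0, cval=0)
        ctv = BinaryMask(voxels=(m > 0.5).astype(np.uint8),
                         spacing=case.ctv.spacing)
    return MultiPhaseCase(case_id=case.case_id, nect=img(case.nect),
                          cect=img(case.cect), ctv=ctv)


def compute_window(shape, patch_size, mode: str = "center",
                   rng: Optional[np.random.Generator] = None):
    """Per-axis (start, stop, pad_before, pad_after) realizing the patch."""
    if mode not in ("center", "random"):
        raise ValueError(f"unknown crop mode {mode!r}")
    window = []
    for n, p in zip(shape, patch_size):
        if n >= p:
            if mode == "random" and n > p:
                start = int(rng.integers(0, n - p + 1))
            else:
                start = (n - p) // 2
            window.append((start, start + p, 0, 0))
        else:
            before = (p - n) // 2
            window.append((0, n, before, p - n - before))
    return tuple(window)


def apply_window(data: np.ndarray, window, pad_value) -> np.ndarray:
    sl = tuple(slice(a, b) for a, b, _, _ in window)
    pads = tuple((pb, pa) for _, _, pb, pa in window)
    out = data[sl]
    if any(pb or pa for pb, pa in pads):
        out = np.pad(out, pads, mode="constant", constant_values=pad_value)
    return out


def undo_window(patch: np.ndarray, window, orig_shape,
                fill=0) -> np.ndarray:
    """Map a patch-sized grid back onto the original grid."""
    out = np.full(orig_shape, fill, dtype=patch.dtype)
    inner = tuple(slice(pb, pb + (b - a)) for (a, b, pb, _) in window)
    outer = tuple(slice(a, b) for a, b, _, _ in window)
    out[outer] = patch[inner]
    return out


def crop_or_pad(case: MultiPhaseCase, patch_size, mode: str = "center",
                seed: Optional[int] = None) -> MultiPhaseCase:
    """Crop/pad every grid of the case to exactly ``patch_size``.

    One shared window; image padding uses each image's minimum (the
    bottom of its clipped intensity range), mask padding is 0.  With
    ``mode='random'`` the window is drawn from the given seed.
    """
    rng = np.random.default_rng(seed) if mode == "random" else None
    window = compute_window(case.shape, patch_size, mode, rng)

    def img(v):
        data = apply_window(v.voxels, window, float(v.voxels.min()))
        return ImageVolume(voxels=data, spacing=v.spacing, phase=v.phase,
                           case_id=v.case_id)

    ctv = None
    if case.ctv is not None:
        ctv = BinaryMask(voxels=apply_window(case.ctv.voxels, window, 0),
                         spacing=case.ctv.spacing)
    return MultiPhaseCase(case_id=case.case_id, nect=img(case.nect),
                          cect=img(case.cect), ctv=ctv)
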