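"""Synthetic two-phase phantom generator.

Each phantom emulates the statistical structure the segmentation method
relies on: a large, smooth, elongated soft-tissue target (the clinical
target volume) with *low* contrast against background in the
non-contrast phase, plus bright tubular "vessel" structures hugging the
target's outer boundary that are visible *only* in the contrast phase —
the cue that anchors the target boundary clinically.  Additive Gaussian
noise and a smooth low-frequency intensity field stand in for scanner
noise and soft-tissue inhomogeneity.

The target is a tapered elliptical tube along the superior-inferior
(slice) axis; its length and volume are drawn from ranges matching real
postoperative pelvic targets (default: length 160-200 mm, volume
450-900 cm^3 at the full 40x224x192, (5,1,1) mm geometry).  Vessels are
constant-radius tubes whose centrelines track the target boundary at a
small inward offset (2-6 mm).  With ``contrast_vessel_c = 0`` the two
phases are bit-identical — the designed control for attributing
two-branch fusion gains to the contrast-only signal.

Intensities are abstract units standing in for HU; the preprocessing
chain treats them identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import BinaryMask, ImageVolume, MultiPhaseCase, write_volume

__all__ = ["PhantomSpec", "generate_case", "generate_split", "load_manifest"]


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int, int] = (40, 224, 192)
    spacing: Tuple[float, float, float] = (5.0, 1.0, 1.0)
    extent_range_mm: Tuple[float, float] = (160.0, 200.0)
    volume_range_cm3: Tuple[float, float] = (450.0, 900.0)
    aspect_range: Tuple[float, float] = (0.85, 1.2)
    center_drift_mm: float = 8.0
    taper: float = 0.4
    n_vessels: int = 2
    vessel_radius_mm: float = 1.5
    vessel_offset_range_mm: Tuple[float, float] = (2.0, 6.0)
    background: float = 30.0
    contrast_n: float = 25.0
    contrast_vessel_c: float = 200.0
    noise_sd: float = 15.0
    edge_blur_mm: float = 2.0
    lowfreq_amp: float = 10.0
    lowfreq_sigma_mm: float = 40.0

    def __post_init__(self):
        if any(v <= 0 for v in (self.vessel_radius_mm, self.noise_sd,
                                self.contrast_n)):
            raise ValueError("radii, contrasts and noise_sd must be positive")
        if self.contrast_vessel_c < 0:
            raise ValueError("vessel contrast must be non-negative")
        if self.vessel_offset_range_mm[0] < self.vessel_radius_mm:
            raise ValueError("vessel offset must be at least the vessel radius "
                             "so tubes stay inside the target")

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Reduced geometry for fast CPU experiments and tests."""
        kw = dict(shape=(16, 64, 64), extent_range_mm=(50.0, 70.0),
                  volume_range_cm3=(20.0, 40.0), center_drift_mm=4.0,
                  n_vessels=2, vessel_offset_range_mm=(2.0, 5.0),
                  lowfreq_sigma_mm=20.0)
        kw.update(overrides)
        return cls(**kw)


def _target_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Draw the tube geometry: slice range, per-slice radii and centres."""
    nz_grid, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    length = rng.uniform(*spec.extent_range_mm)
    nz = int(round(length / dz))
    if nz < 2 or nz > nz_grid:
        raise ValueError(
            f"target of {length:.0f} mm ({nz} slices) does not fit the "
            f"{nz_grid}-slice grid")
    z0 = int(rng.integers(0, nz_grid - nz + 1))
    t = np.linspace(-1.0, 1.0, nz)
    scale = 1.0 - spec.taper * t ** 2
    # volume target drawn with a 10% inner margin to absorb rasterization
    lo, hi = spec.volume_range_cm3
    vol_mm3 = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo)) * 1000.0
    eff_len = float(np.sum(scale ** 2)) * dz
    aspect = rng.uniform(*spec.aspect_range)
    rx = np.sqrt(vol_mm3 / (np.pi * aspect * eff_len))
    ry = aspect * rx
    max_ry = (ny * dy) / 2.0 - spec.center_drift_mm - 2.0
    max_rx = (nx * dx) / 2.0 - spec.center_drift_mm - 2.0
    if ry > max_ry or rx > max_rx:
        raise ValueError(
            f"target radii ({ry:.1f}, {rx:.1f}) mm do not fit the in-plane "
            f"grid ({ny * dy:.0f} x {nx * dx:.0f} mm)")
    # smooth quadratic centre drift in mm
    cy0, cx0 = ny * dy / 2.0, nx * dx / 2.0
    a = rng.uniform(-spec.center_drift_mm, spec.center_drift_mm, size=4)
    cy = cy0 + a[0] * t + a[1] * t ** 2
    cx = cx0 + a[2] * t + a[3] * t ** 2
    return z0, nz, scale * ry, scale * rx, cy, cx


def generate_case(spec: PhantomSpec, seed: int) -> MultiPhaseCase:
    """Generate one paired two-phase case with ground truth, bit-deterministic per seed."""
    rng = np.random.default_rng(seed)
    nz_grid, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    z0, nz, ry, rx, cy, cx = _target_geometry(spec, rng)

    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    mask = np.zeros(spec.shape, dtype=np.uint8)
    for k in range(nz):
        mask[z0 + k] = (((Y - cy[k]) / ry[k]) ** 2
                        + ((X - cx[k]) / rx[k]) ** 2) <= 1.0

    # vessels: tubes whose centrelines ride a shell just inside the surface
    vessel = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_vessels):
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        omega = rng.uniform(-0.8, 0.8)
        offset = rng.uniform(*spec.vessel_offset_range_mm)
        t = np.linspace(-1.0, 1.0, nz)
        for k in range(nz):
            th = theta0 + omega * t[k]
            vy, vx = ry[k] * np.sin(th), rx[k] * np.cos(th)
            r_local = float(np.hypot(vy, vx))
            shrink = max(0.0, 1.0 - offset / r_local)
            py = cy[k] + vy * shrink
            px = cx[k] + vx * shrink
            disc = (Y - py) ** 2 + (X - px) ** 2 <= spec.vessel_radius_mm ** 2
            vessel[z0 + k] |= disc
    vessel &= mask.astype(bool)

    soft = gaussian_filter(mask.astype(np.float64),
                           sigma=[spec.edge_blur_mm / s for s in spec.spacing])
    lowfreq = gaussian_filter(rng.normal(size=spec.shape),
                              sigma=[spec.lowfreq_sigma_mm / s for s in spec.spacing])
    sd = lowfreq.std()
    if sd > 0:
        lowfreq *= spec.lowfreq_amp / sd
    noise = rng.normal(0.0, spec.noise_sd, size=spec.shape)
    phase_n = spec.background + spec.contrast_n * soft + lowfreq + noise
    phase_c = phase_n + spec.contrast_vessel_c * vessel

    cid = f"case_{seed:05d}"
    return MultiPhaseCase(
        case_id=cid,
        nect=ImageVolume(voxels=phase_n.astype(np.float32),
                         spacing=spec.spacing, phase="N", case_id=cid),
        cect=ImageVolume(voxels=phase_c.astype(np.float32),
                         spacing=spec.spacing, phase="C", case_id=cid),
        ctv=BinaryMask(voxels=mask, spacing=spec.spacing),
    )


def generate_split(n_train: int, n_val: int, n_test: int, spec: PhantomSpec,
                   seed: int, out_dir) -> str:
    """Generate disjoint seeded splits on disk; returns the manifest path.

    Each case gets its own derived seed; regenerating from the manifest
    seeds reproduces every file bit-for-bit.
    """
    if min(n_train, n_val, n_test) < 0 or n_train + n_val + n_test == 0:
        raise ValueError("split sizes must be non-negative and non-empty")
    os.makedirs(out_dir, exist_ok=True)
    counts = [("train", n_train), ("val", n_val), ("test", n_test)]
    total = n_train + n_val + n_test
    case_seeds = (np.random.SeedSequence(seed).generate_state(total)
                  % np.uint32(2 ** 31)).astype(np.int64)
    rows = []
    i = 0
    for split, n in counts:
        for _ in range(n):
            cseed = int(case_seeds[i])
            case = generate_case(spec, cseed)
            cid = f"{split}_{i:03d}"
            paths = {}
            for key, obj in (("nect", case.nect), ("cect", case.cect),
                             ("ctv", case.ctv)):
                fname = f"{cid}_{key}.nii.gz"
                write_volume(obj, os.path.join(out_dir, fname))
                paths[key] = fname
            rows.append(dict(id=cid, split=split, seed=cseed, **paths))
            i += 1
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "split", "seed", "nect", "cect", "ctv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df
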