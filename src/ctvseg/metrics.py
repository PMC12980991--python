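"""Segmentation evaluation suite.

Volumetric Dice (DSC), the average (symmetric) distance in millimetres,
and the contour Dice similarity coefficient (CDSC) — a per-slice 2-D
Dice computed between thickness-t bands along the outer contours of the
prediction and ground-truth masks, averaged over slices.  The contour
band of a slice is the inner band: mask pixels whose Euclidean distance
to the background does not exceed the thickness (equivalently the mask
minus its Euclidean erosion at that radius).

The directed average distance is implemented in its voxel-set form —
the mean over *all* foreground voxels of one mask of the minimum
physical distance to the other mask's foreground — with the
conventional surface-restricted variant available behind a flag.

A Pearson-correlation helper relates per-case metric values to clinical
modification times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import binary_erosion, distance_transform_edt, generate_binary_structure

__all__ = [
    "MetricReport",
    "dsc",
    "asd",
    "assd",
    "contour_band",
    "cdsc",
    "metric_time_correlation",
    "evaluate_pair",
    "DEFAULT_CDSC_THICKNESSES_MM",
]

# thickness sweep used for reporting (mm)
DEFAULT_CDSC_THICKNESSES_MM = tuple(range(2, 10))


def _fg(mask) -> np.ndarray:
    return np.asarray(getattr(mask, "voxels", mask)) > 0.5


def _check_shapes(p, g):
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")


@dataclass
class MetricReport:
    """Per-case evaluation record."""

    case_id: str
    dsc: float
    assd_mm: float
    cdsc_by_thickness: Dict[float, float]


def dsc(p_mask, g) -> float:
    """Volumetric Dice overlap ``2|P∩G| / (|P|+|G|)``.

    Both masks empty -> 1.0; exactly one empty -> 0.0.
    """
    p, g = _fg(p_mask), _fg(g)
    _check_shapes(p, g)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    if np_ == 0 or ng == 0:
        return 0.0
    return 2.0 * int((p & g).sum()) / (np_ + ng)


def _surface(fg: np.ndarray) -> np.ndarray:
    struct = generate_binary_structure(fg.ndim, 1)
    return fg & ~binary_erosion(fg, structure=struct, border_value=0)


def asd(p_mask, g, spacing=(1.0, 1.0, 1.0), surface: bool = False) -> float:
    """Directed average distance from P to G in mm.

    Default is the voxel-set form: the mean over every foreground voxel
    of P of its minimum Euclidean distance to G's foreground.  With
    ``surface=True`` both masks are first restricted to their surface
    voxels (the conventional surface ASD).
    """
    p, gm = _fg(p_mask), _fg(g)
    _check_shapes(p, gm)
    if not p.any() or not gm.any():
        raise ValueError("ASD undefined for empty mask")
    if surface:
        p, gm = _surface(p), _surface(gm)
    dist_to_g = distance_transform_edt(~gm, sampling=tuple(map(float, spacing)))
    return float(dist_to_g[p].mean())


def assd(p_mask, g, spacing=(1.0, 1.0, 1.0), surface: bool = False) -> float:
    """Symmetric average distance: ``(ASD(P,G) + ASD(G,P)) / 2``."""
    return 0.5 * (asd(p_mask, g, spacing, surface)
                  + asd(g, p_mask, spacing, surface))


def contour_band(mask_slice, thickness_mm: float,
                 in_plane_spacing=(1.0, 1.0)) -> np.ndarray:
    """Inner contour band of a 2-D mask slice.

    Pixels of the mask whose Euclidean distance to the background is at
    most ``thickness_mm`` — the mask minus its erosion at that radius.
    An empty slice yields an empty band.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    m = _fg(mask_slice)
    if m.ndim != 2:
        raise ValueError("contour_band expects a 2-D slice")
    if not m.any():
        return np.zeros_like(m)
    # the slice border counts as background so a full-slice mask still
    # has an outer contour; one padding ring realizes that convention
    padded = np.pad(m, 1)
    d = distance_transform_edt(padded,
                               sampling=tuple(map(float, in_plane_spacing)))
    return m & (d[1:-1, 1:-1] <= thickness_mm)


def cdsc(p_mask, g, thickness_mm: float, spacing=(1.0, 1.0, 1.0)) -> float:
    """Contour Dice: mean per-slice 2-D Dice of the two contour bands.

    Slices (along the first axis) where both bands are empty are
    skipped; a slice where exactly one band is empty scores 0.  Raises
    if no slice has any band.
    """
    p, gm = _fg(p_mask), _fg(g)
    _check_shapes(p, gm)
    in_plane = tuple(map(float, spacing[1:]))
    scores = []
    for k in range(p.shape[0]):
        bp = contour_band(p[k], thickness_mm, in_plane)
        bg = contour_band(gm[k], thickness_mm, in_plane)
        ep, eg = not bp.any(), not bg.any()
        if ep and eg:
            continue
        if ep or eg:
            scores.append(0.0)
        else:
            scores.append(2.0 * int((bp & bg).sum())
                          / (int(bp.sum()) + int(bg.sum())))
    if not scores:
        raise ValueError("CDSC undefined: no slice has a contour band")
    return float(np.mean(scores))


def metric_time_correlation(metric_values: Sequence[float],
                            times: Sequence[float]) -> float:
    """Sample Pearson correlation between per-case metrics and times."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(times, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 cases")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_pair(case_id: str, p_mask, g, spacing,
                  thicknesses_mm=DEFAULT_CDSC_THICKNESSES_MM) -> MetricReport:
    """Full per-case report: DSC, ASSD (mm) and CDSC at each thickness."""
    d = dsc(p_mask, g)
    try:
        a = assd(p_mask, g, spacing)
    except ValueError:
        a = float("nan")
    bands = {}
    for t in thicknesses_mm:
        try:
            bands[float(t)] = cdsc(p_mask, g, float(t), spacing)
        except ValueError:
            bands[float(t)] = float("nan")
    return MetricReport(case_id=case_id, dsc=d, assd_mm=a,
                        cdsc_by_thickness=bands)
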