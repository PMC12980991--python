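"""Evaluation metrics on a controlled mask pair, plus the CDSC sweep.

An 11x11 square shifted by one pixel: volumetric DSC is high, but the
contour-band Dice at small thickness is more sensitive to the boundary
shift — the property that makes it track clinical editing effort.
"""

import numpy as np

from ctvseg import assd, cdsc, dsc, metric_time_correlation

p = np.zeros((3, 16, 16), np.uint8)
g = np.zeros((3, 16, 16), np.uint8)
for k in range(3):
    p[k, 2:13, 2:13] = 1
    g[k, 2:13, 3:14] = 1  # ground truth shifted one pixel right

spacing = (5.0, 1.0, 1.0)
print(f"DSC:  {dsc(p, g):.4f}")
print(f"ASSD: {assd(p, g, spacing):.4f} mm")
for t in (2, 4, 8):
    print(f"CDSC {t} mm: {cdsc(p, g, t, spacing):.4f}")
# the volumetric Dice barely notices the 1 mm shift; the thin contour
# band penalizes it hard, converging back toward the slice Dice as the
# band thickens into the full mask

dscs = [0.80, 0.85, 0.87, 0.90, 0.95]
minutes = [5.0, 4.0, 4.5, 2.0, 1.0]
r = metric_time_correlation(dscs, minutes)
print(f"\nPearson r (metric vs modification minutes): {r:.3f}")
# a strongly negative correlation: better contours need less editing
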