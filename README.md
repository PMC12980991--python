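# ctvseg

Lightweight multi-phase CT segmentation of the postoperative pelvic
clinical target volume (CTV), for researchers building and evaluating
radiotherapy auto-contouring methods.

The CTV for postoperative pelvic radiotherapy is a large, low-contrast
region whose boundary is anchored by the iliac vessels — structures
clearly visible only on contrast-enhanced CT (CECT), while treatment
planning happens on non-contrast CT (NECT).  `ctvseg` implements a
two-branch segmentation network that fuses both phases, trained with a
boundary-aware loss and evaluated with contour-sensitive metrics:

* **NCLNet** — one U-shape feature extractor per phase (channel widths
  32/64/128/256/320), with every convolution unit above 32 input
  channels replaced by a three-layer bottleneck (1×1×1 compress to
  c/8, 3×3×3, 1×1×1 restore).  The bottleneck's weight count
  `c·c/8 + (c/8)²·27 + (c/8)·c_out` is ~40× smaller than the plain
  `c·c_out·27` at `c_out = c`; the full two-branch 3-D model totals
  5.7 M trainable parameters.  A spatial-attention module fuses the two
  feature streams; three sigmoid heads supervise the N-branch,
  C-branch and fused features.
* **Boundary-aware multi-phase loss** — per head,
  `(1 − 2Σwᵢpᵢqᵢ/(Σpᵢ+Σqᵢ+ε)) + BCE(p, q)`, where the per-voxel
  weight `w = 2 − D(F)/max D(F) − D(B)/max D(B)` is built from the
  Euclidean distance transforms of the ground-truth foreground and
  background and peaks at their interface.
* **Metrics** — volumetric Dice (DSC), average symmetric distance in
  mm (ASSD, voxel-set form as defined, surface variant available), and
  the contour Dice (CDSC): per-slice 2-D Dice of thickness-t bands
  along the masks' outer contours, reported for 2–9 mm, plus a
  Pearson utility relating metrics to clinical modification times.
* **Phantom generator** — seeded synthetic two-phase cases: an
  elongated low-contrast target with bright boundary-hugging vessel
  tubes visible only in the contrast phase, so the whole pipeline runs
  end-to-end at desk scale with known ground truth.

The network, gradients and optimizer run on a compact NumPy
reverse-mode autodiff engine included in the package
(`ctvseg.autodiff`); every operator's gradient is tested against
finite differences.

## Worked example

```python
import numpy as np
import ctvseg as cs

# complexity of the pinned two-branch 3-D model
model = cs.build_nclnet(cs.NCLNetConfig(), seed=0)
print(cs.count_parameters(model))                  # 5694917  (5.7 M)
print(cs.plain_conv_param_count(64, 64)
      / cs.bottleneck_param_count(64, 64, 8))      # 40.186   (1728/43)

# the distance-penalty weights of a toy mask
fields = cs.distance_fields(np.array([0, 1, 1, 1, 0]).reshape(1, 1, 5),
                            spacing=(1, 1, 1))
print(fields.w.ravel())                            # [1.  1.5 1.  1.5 1.]

# contour-sensitive evaluation of a 1-pixel boundary shift
p = np.zeros((3, 16, 16), np.uint8); g = p.copy()
p[:, 2:13, 2:13] = 1; g[:, 2:13, 3:14] = 1
print(cs.dsc(p, g))                                # 0.9091
print(cs.cdsc(p, g, 2, (5, 1, 1)))                 # 0.7500
```

The volumetric Dice barely notices the 1 mm contour shift (0.909); the
2 mm contour band penalizes it hard (0.750) — the sensitivity that
makes CDSC track how much editing a predicted contour needs.  The
weight vector shows the penalty peaking on the voxels flanking the
foreground/background interface.

Narrative scripts in `examples/` cover each capability: phantom
generation, complexity accounting, the boundary loss, the metric
suite, a tiny end-to-end training run (`train_tiny.py`, a few minutes
on CPU: loss 3.93 → −0.40 over 150 iterations, held-out DSC 0.64),
and a longer directional study of fusion and the distance penalty
(`ablation_echo.py`).  A `ctvseg` command-line tool wraps the same
pipeline (`phantom`, `train`, `predict`, `evaluate`, `count`
subcommands) for shell use; `ctvseg evaluate` writes a per-case CSV
with `dsc`, `assd_mm` and `cdsc_2mm`…`cdsc_9mm` columns plus mean and
standard-deviation rows.

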