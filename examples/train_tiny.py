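"""End-to-end desk-scale run: phantoms -> training -> prediction -> metrics.

Trains a tiny two-branch model on a handful of 8x32x32 phantoms for a
few minutes on one CPU, then segments a held-out case and scores it.
"""

import tempfile

import numpy as np

from ctvseg import PhantomSpec, assd, cdsc, dsc, generate_split
from ctvseg.nclnet import NCLNetConfig, build_nclnet
from ctvseg.preprocess import IntensityStats
from ctvseg.train import TrainConfig, load_cases, predict, train

spec = PhantomSpec.desk(shape=(8, 32, 32), extent_range_mm=(25.0, 35.0),
                        volume_range_cm3=(4.0, 8.0), center_drift_mm=2.0)
config = TrainConfig(epochs=6, iters_per_epoch=25, batch_size=1,
                     patch_size=(8, 32, 32), seed=0, mode="nence")

with tempfile.TemporaryDirectory() as d:
    manifest = generate_split(4, 2, 1, spec, seed=21, out_dir=d)
    model = build_nclnet(NCLNetConfig.tiny(), seed=0)
    result = train(model, manifest, config)
    print(f"loss {result.loss_trace[0]:.3f} -> {result.loss_trace[-1]:.3f} "
          f"over {len(result.loss_trace)} iterations")
    print("val DSC per epoch:", [round(v, 3) for v in result.val_dsc])

    train_cases = load_cases(manifest, "train")
    stats = IntensityStats.from_volumes(
        [c.nect for c in train_cases] + [c.cect for c in train_cases])
    test_case = load_cases(manifest, "test")[0]
    mask, _ = predict(result.model, test_case, stats, config.patch_size)
    print(f"\nheld-out case: DSC {dsc(mask.voxels, test_case.ctv.voxels):.3f}, "
          f"ASSD {assd(mask.voxels, test_case.ctv.voxels, spec.spacing):.2f} mm, "
          f"CDSC-8mm {cdsc(mask.voxels, test_case.ctv.voxels, 8, spec.spacing):.3f}")
# the loss drops steadily and the fused head segments the held-out
# phantom well above chance after ~150 iterations of CPU training
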