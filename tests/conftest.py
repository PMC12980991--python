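"""Shared fixtures: tiny phantom datasets and a seed-pinned overfit run.

The expensive single-case overfit training is session-scoped so the
optimization sanity tests and the acceptance checks reuse one run.
"""

import numpy as np
import pytest

import ctvseg as cs
from ctvseg import preprocess as pp
from ctvseg.autodiff import no_grad
from ctvseg.nclnet import NCLNetConfig, build_nclnet
from ctvseg.train import TrainConfig, _forward, _normalize_case, load_cases, train

OVERFIT_SPEC = dict(shape=(8, 32, 32), extent_range_mm=(25.0, 35.0),
                    volume_range_cm3=(4.0, 8.0), center_drift_mm=2.0)


@pytest.fixture(scope="session")
def tiny_spec():
    return cs.PhantomSpec.desk(**OVERFIT_SPEC)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_spec):
    """One train + one val phantom on disk with a manifest."""
    d = tmp_path_factory.mktemp("tinydata")
    manifest = cs.generate_split(1, 1, 0, tiny_spec, seed=7, out_dir=str(d))
    return manifest


@pytest.fixture(scope="session")
def overfit_run(tmp_path_factory, tiny_spec):
    """Seed-pinned 300-iteration overfit of a tiny model on one phantom.

    Augmentation is disabled so the network sees one fixed patch; the
    returned dict carries the result, the training case and the
    per-head training DSC of the final model.
    """
    d = tmp_path_factory.mktemp("overfit")
    manifest = cs.generate_split(1, 0, 0, tiny_spec, seed=7, out_dir=str(d))
    config = TrainConfig(epochs=10, iters_per_epoch=30, batch_size=1,
                         patch_size=(8, 32, 32), seed=0, mode="nence",
                         flip_prob=0.0, rot_range_deg=(0.0, 0.0))
    model = build_nclnet(NCLNetConfig.tiny(), seed=0)
    result = train(model, manifest, config)

    case = load_cases(manifest, "train")[0]
    stats = pp.IntensityStats.from_volumes([case.nect, case.cect])
    patch = pp.crop_or_pad(_normalize_case(case, stats, (5, 1, 1)),
                           (8, 32, 32), "center")
    with no_grad():
        triplet = _forward(result.model, [patch], "nence")
    dscs = {}
    for name, p in (("ne", triplet.p_ne), ("ce", triplet.p_ce),
                    ("fuse", triplet.p_fuse)):
        pred = (p.data[0, 0] > 0.5).astype(np.uint8)
        dscs[name] = cs.dsc(pred, patch.ctv.voxels)
    return dict(result=result, config=config, manifest=manifest,
                train_dsc=dscs)


def random_mask(rng, shape, p=0.4):
    """A random binary mask guaranteed non-trivial (mixed fg/bg)."""
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if 0 < m.sum() < m.size:
            return m
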