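"""Training and inference loops.

The recipe: SGD with momentum 0.95, initial learning rate 0.01 decaying
linearly to zero over the epochs, mini-batches of 2 random training
cases (uniform with replacement), per-sample random flip/rotation
augmentation and a random fixed-size crop, and the boundary-aware
multi-phase loss over the available prediction heads.  Distance-penalty
weights are recomputed from the ground-truth mask of each cropped patch
(recomputation after the geometric transform is exact; warping a
distance field is not).  The checkpoint with the best validation Dice
of the fused head (threshold 0.5) is kept.  Every random draw derives
from the single config seed, so a run's loss trace is bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np
import yaml

from . import preprocess as pp
from .autodiff import no_grad
from .baml import baml_loss, distance_fields
from .core import BinaryMask, MultiPhaseCase, read_mask, read_volume
from .metrics import dsc
from .nclnet import NCLNet, NCLNetConfig, build_nclnet
from .phantom import load_manifest

__all__ = [
    "TrainConfig",
    "TrainResult",
    "lr_at",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "load_cases",
]

MODES = ("nect", "cect", "nence")


@dataclass
class TrainConfig:
    epochs: int = 200
    iters_per_epoch: int = 250
    batch_size: int = 2
    lr0: float = 0.01
    momentum: float = 0.95
    patch_size: Tuple[int, int, int] = (40, 224, 192)
    seed: int = 0
    use_bottleneck: bool = True
    use_distance_penalty: bool = True
    mode: str = "nence"
    flip_prob: float = 0.5
    rot_range_deg: Tuple[float, float] = (-15.0, 15.0)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if min(self.epochs, self.iters_per_epoch, self.batch_size) <= 0:
            raise ValueError("epochs, iterations and batch size must be positive")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        kw = dict(epochs=20, iters_per_epoch=20, patch_size=(16, 64, 64))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainResult:
    model: NCLNet
    loss_trace: List[float]          # one entry per iteration
    epoch_loss: List[float]
    val_dsc: List[float]
    lr_schedule: List[float]
    best_epoch: int
    checkpoint_path: Optional[str] = None


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Linear decay: ``lr0 * (1 - epoch/epochs)``; zero at the final boundary."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    return config.lr0 * (1.0 - epoch / config.epochs)


class _SGD:
    def __init__(self, params, momentum: float):
        self.params = list(params)
        self.momentum = momentum
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def load_cases(manifest_path, split: Optional[str] = None) -> List[MultiPhaseCase]:
    """Materialize manifest rows as in-memory cases."""
    df = load_manifest(manifest_path)
    if split is not None:
        df = df[df["split"] == split]
    base = os.path.dirname(os.path.abspath(manifest_path))
    cases = []
    for row in df.itertuples():
        cases.append(MultiPhaseCase(
            case_id=row.id,
            nect=read_volume(os.path.join(base, row.nect), "N", row.id),
            cect=read_volume(os.path.join(base, row.cect), "C", row.id),
            ctv=read_mask(os.path.join(base, row.ctv)),
        ))
    return cases


def _normalize_case(case: MultiPhaseCase, stats: pp.IntensityStats,
                    target_spacing) -> MultiPhaseCase:
    nect = pp.resample(pp.clip_and_normalize(case.nect, stats), target_spacing)
    cect = pp.resample(pp.clip_and_normalize(case.cect, stats), target_spacing)
    ctv = pp.resample(case.ctv, target_spacing) if case.ctv is not None else None
    return MultiPhaseCase(case.case_id, nect, cect, ctv)


def _model_inputs(case: MultiPhaseCase, mode: str):
    xn = case.nect.voxels[None, None].astype(np.float32)
    xc = case.cect.voxels[None, None].astype(np.float32)
    if mode == "nence":
        return (xn, xc)
    return (xn,) if mode == "nect" else (xc,)


def _forward(model: NCLNet, batch_cases, mode: str):
    ins = [_model_inputs(c, mode) for c in batch_cases]
    stacked = tuple(np.concatenate([b[i] for b in ins], axis=0)
                    for i in range(len(ins[0])))
    return model(*stacked)


def train(model: NCLNet, manifest_path, config: TrainConfig,
          out_dir=None, stats: Optional[pp.IntensityStats] = None,
          pre_cfg: Optional[pp.PreprocessConfig] = None) -> TrainResult:
    """Run the full training recipe; returns the best-validation model.

    ``stats`` (clip bounds + moments) are computed from the pooled
    training-set intensities when not supplied, and persisted alongside
    the checkpoint when ``out_dir`` is given.
    """
    pre_cfg = pre_cfg or pp.PreprocessConfig(patch_size=tuple(config.patch_size))
    train_cases = load_cases(manifest_path, "train")
    val_cases = load_cases(manifest_path, "val")
    if not train_cases:
        raise ValueError("empty training dataset")
    if stats is None:
        stats = pp.IntensityStats.from_volumes(
            [c.nect for c in train_cases] + [c.cect for c in train_cases],
            pre_cfg.clip_lo_pct, pre_cfg.clip_hi_pct)
    train_cases = [_normalize_case(c, stats, pre_cfg.target_spacing)
                   for c in train_cases]
    val_cases = [_normalize_case(c, stats, pre_cfg.target_spacing)
                 for c in val_cases]
    val_patches = [pp.crop_or_pad(c, config.patch_size, "center")
                   for c in val_cases]

    rng = np.random.default_rng(config.seed)
    opt = _SGD(model.parameters(), config.momentum)
    loss_trace: List[float] = []
    epoch_loss: List[float] = []
    val_hist: List[float] = []
    lr_hist: List[float] = []
    best = (-1.0, 0, None)  # (val dsc, epoch, state)
    log_lines: List[str] = []

    for epoch in range(config.epochs):
        lr = lr_at(epoch, config)
        lr_hist.append(lr)
        losses = []
        for it in range(config.iters_per_epoch):
            batch = []
            for _ in range(config.batch_size):
                case = train_cases[int(rng.integers(len(train_cases)))]
                case = pp.augment(case, int(rng.integers(2 ** 31)),
                                  config.flip_prob, config.rot_range_deg)
                case = pp.crop_or_pad(case, config.patch_size, "random",
                                      int(rng.integers(2 ** 31)))
                batch.append(case)
            q = np.stack([c.ctv.voxels for c in batch])[:, None].astype(float)
            if config.use_distance_penalty:
                w = np.stack([
                    distance_fields(c.ctv.voxels, c.spacing).w for c in batch
                ])[:, None]
            else:
                w = None
            triplet = _forward(model, batch, config.mode)
            loss = baml_loss(triplet, q, fields=w,
                             use_distance_penalty=config.use_distance_penalty)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch} iter {it} "
                    f"(lr={lr:.5f}); aborting")
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(value)
            loss_trace.append(value)
            log_lines.append(f"epoch={epoch} iter={it} loss={value:.6f} lr={lr:.6f}")
        epoch_loss.append(float(np.mean(losses)))
        vd = _validation_dsc(model, val_patches, config.mode)
        val_hist.append(vd)
        log_lines.append(
            f"epoch={epoch} mean_loss={epoch_loss[-1]:.6f} lr={lr:.6f} "
            f"val_dsc={vd:.4f}")
        if vd > best[0]:
            best = (vd, epoch, [p.data.copy() for p in model.parameters()])

    if best[2] is not None:
        for p, d in zip(model.parameters(), best[2]):
            p.data = d
    ckpt = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        ckpt = os.path.join(out_dir, "checkpoint.npz")
        save_checkpoint(model, ckpt)
        stats.save(os.path.join(out_dir, "intensity_stats.txt"))
        with open(os.path.join(out_dir, "train_log.txt"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        with open(os.path.join(out_dir, "train_config.yaml"), "w") as fh:
            yaml.safe_dump(asdict(config), fh)
    return TrainResult(model=model, loss_trace=loss_trace,
                       epoch_loss=epoch_loss, val_dsc=val_hist,
                       lr_schedule=lr_hist, best_epoch=best[1],
                       checkpoint_path=ckpt)


def _validation_dsc(model: NCLNet, val_patches, mode: str) -> float:
    if not val_patches:
        return float("nan")
    scores = []
    with no_grad():
        for case in val_patches:
            triplet = _forward(model, [case], mode)
            pred = (triplet.p_fuse.data[0, 0] > 0.5).astype(np.uint8)
            scores.append(dsc(pred, case.ctv.voxels))
    return float(np.mean(scores))


def save_checkpoint(model: NCLNet, path) -> None:
    """Persist weights (npz) plus a self-describing plain-text config."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(asdict(model.cfg), fh)


def load_checkpoint(path) -> NCLNet:
    with open(str(path) + ".yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in ("widths", "stage_strides"):
        if raw.get(key) is not None:
            raw[key] = tuple(tuple(s) if isinstance(s, list) else s
                             for s in raw[key])
    cfg = NCLNetConfig(**raw)
    model = build_nclnet(cfg, seed=0)
    with np.load(path) as data:
        params = model.parameters()
        if len(data.files) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr
    return model


def predict(model: NCLNet, case: MultiPhaseCase, stats: pp.IntensityStats,
            patch_size, mode: str = "nence",
            target_spacing=(5.0, 1.0, 1.0)):
    """Segment one case; returns (mask on the original grid, triplet).

    The case is normalized and resampled with the *training* statistics,
    centre-cropped/padded to the patch size, passed through the model,
    and the fused probability map is thresholded at 0.5 and mapped back
    through the crop and resampling onto the input grid.
    """
    orig_shape = case.shape
    orig_spacing = case.spacing
    norm = _normalize_case(case, stats, target_spacing)
    window = pp.compute_window(norm.shape, patch_size, "center")
    patch = pp.crop_or_pad(norm, patch_size, "center")
    with no_grad():
        triplet = _forward(model, [patch], mode)
    binary = (triplet.p_fuse.data[0, 0] > 0.5).astype(np.uint8)
    on_resampled = pp.undo_window(binary, window, norm.shape)
    mask = BinaryMask(voxels=on_resampled, spacing=norm.spacing)
    if tuple(np.round(orig_spacing, 6)) != tuple(np.round(norm.spacing, 6)):
        mask = pp.resample(mask, orig_spacing)
    if mask.shape != orig_shape:  # rounding in the resample round-trip
        back = pp.compute_window(mask.shape, orig_shape, "center")
        mask = BinaryMask(voxels=pp.apply_window(mask.voxels, back, 0),
                          spacing=orig_spacing)
    return mask, triplet
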