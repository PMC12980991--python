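"""The NCLNet model family.

A lightweight two-branch segmentation network for paired multi-phase CT:
one U-shape feature extractor per phase (Branch-N for the non-contrast
volume, Branch-C for the contrast-enhanced volume), bottleneck blocks
replacing plain convolution units wherever the input channel count
exceeds a threshold, and a spatial-attention fusion module that merges
the two feature streams into a fused prediction.  Three sigmoid heads
supervise the N-branch features, the C-branch features and the fused
features.

The bottleneck block is the parameter-reduction unit: a 1x1x1
compression to ``c / compression`` channels, a 3x3x3 convolution at the
compressed width, and a 1x1x1 restoration.  With compression 8 and
``c_out == c`` its weight count is smaller than a plain 3x3x3
convolution's by a factor of 1728/43 (about 40), independent of ``c``.

Also provided: closed-form weight counters for the plain and bottleneck
units, a trainable-parameter counter and an analytic FLOP counter
(2 multiply-accumulates per convolution weight application; bias,
normalization and activation arithmetic excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat, conv3d, conv_transpose3d, instance_norm

__all__ = [
    "NCLNetConfig",
    "PredictionTriplet",
    "bottleneck_param_count",
    "plain_conv_param_count",
    "build_extractor",
    "build_nclnet",
    "count_parameters",
    "count_flops",
    "stage_shapes",
    "NCLNet",
    "Extractor",
]

# Hidden width of the fusion module's attention stem.  This is the one
# width the architecture leaves open; it is pinned so that the standard
# two-branch 3-D configuration totals 5.7 million trainable parameters
# (5,694,917 with the widths and stride plan below).
DEFAULT_FUSION_HIDDEN = 1344

_DEFAULT_STRIDES_3D = ((1, 2, 2), (1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2))


def _default_strides(dims: int, n_stages: int):
    if dims == 3 and n_stages == 5:
        return _DEFAULT_STRIDES_3D
    if dims == 2:
        return tuple((2, 2) for _ in range(n_stages))
    # generic fallback: pool the anisotropic slice axis only at depth
    out = []
    for i in range(n_stages):
        out.append((1, 2, 2) if i < max(0, n_stages - 3) else (2, 2, 2))
    return tuple(out)


@dataclass(frozen=True)
class NCLNetConfig:
    """Pinned architecture hyper-parameters.

    widths are the encoder stage channel counts; a convolution unit is
    replaced by a bottleneck block when its *input* channel count
    exceeds ``bottleneck_threshold``.  ``stage_strides`` holds one
    per-stage downsampling factor per spatial axis (2-tuples for
    ``dims == 2``).
    """

    dims: int = 3
    widths: tuple = (32, 64, 128, 256, 320)
    bottleneck_threshold: int = 32
    compression: int = 8
    stage_strides: Optional[tuple] = None
    two_branch: bool = True
    in_channels: int = 1
    use_bottleneck: bool = True
    fusion_hidden: int = DEFAULT_FUSION_HIDDEN
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if any(b > a for a, b in zip(self.widths[1:], self.widths[:-1])):
            raise ValueError("widths must be non-decreasing")
        strides = self.stage_strides
        if strides is None:
            strides = _default_strides(self.dims, len(self.widths))
            object.__setattr__(self, "stage_strides", strides)
        if len(strides) != len(self.widths):
            raise ValueError("need one stride tuple per stage")
        if self.use_bottleneck:
            for w in self._bottleneck_inputs():
                if w % self.compression:
                    raise ValueError(
                        f"compression {self.compression} does not divide "
                        f"bottlenecked input width {w}")

    def _bottleneck_inputs(self):
        """Every input channel count that the bottleneck rule applies to."""
        ws = set()
        prev = self.widths[0]
        for w in self.widths:
            for c in (prev, w):
                if c > self.bottleneck_threshold:
                    ws.add(c)
            prev = w
        for w in self.widths[:-1] + (self.widths[0],):
            if 2 * w > self.bottleneck_threshold:
                ws.add(2 * w)
            if w > self.bottleneck_threshold:
                ws.add(w)
        return sorted(ws)

    def strides3(self):
        """Stage strides lifted to 3-D (2-D stages act on (H, W) only)."""
        if self.dims == 3:
            return tuple(tuple(s) for s in self.stage_strides)
        return tuple((1,) + tuple(s) for s in self.stage_strides)

    @classmethod
    def desk(cls, **overrides) -> "NCLNetConfig":
        """Reduced preset preserving every structural rule at test scale."""
        kw = dict(widths=(8, 16, 32, 64, 80), bottleneck_threshold=8,
                  compression=8, fusion_hidden=32)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def tiny(cls, **overrides) -> "NCLNetConfig":
        """Three-stage miniature for fast optimization checks."""
        kw = dict(widths=(4, 8, 16), bottleneck_threshold=4, compression=4,
                  fusion_hidden=8,
                  stage_strides=((1, 2, 2), (2, 2, 2), (2, 2, 2)))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PredictionTriplet:
    """The supervised probability maps.

    Heads that a configuration does not produce are None (never
    zero-filled).  In single-extractor mode the sole head is stored as
    ``p_fuse``: it is the deliverable prediction.
    """

    p_ne: Optional[Tensor] = None
    p_ce: Optional[Tensor] = None
    p_fuse: Optional[Tensor] = None

    def heads(self):
        return [p for p in (self.p_ne, self.p_ce, self.p_fuse) if p is not None]


# -- closed-form weight counters ------------------------------------------

def _kernel_elems(dims: int) -> int:
    return 27 if dims == 3 else 9


def plain_conv_param_count(c: int, c_out: int, dims: int = 3) -> int:
    """Weight count of a plain 3^dims convolution (no bias)."""
    if c <= 0 or c_out <= 0:
        raise ValueError("channel counts must be positive")
    return c * c_out * _kernel_elems(dims)


def bottleneck_param_count(c: int, c_out: int, compression: int = 8,
                           dims: int = 3) -> int:
    """Weight count of the three-layer bottleneck block (no bias).

    compress 1x1x1 (c -> c/r), 3x3x3 at c/r, restore 1x1x1 (c/r -> c_out).
    """
    if c % compression:
        raise ValueError(f"compression {compression} does not divide c={c}")
    m = c // compression
    return c * m + m * m * _kernel_elems(dims) + m * c_out


# -- layers ----------------------------------------------------------------

class Module:
    """Parameter container with recursive traversal."""

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def modules(self):
        yield self
        for c in self._children():
            yield from c.modules()

    def parameters(self):
        ps = [v for v in self.__dict__.values()
              if isinstance(v, Tensor) and v.requires_grad]
        for c in self._children():
            ps.extend(c.parameters())
        return ps


def _kaiming(rng: np.random.Generator, shape, fan_in: int,
             slope: float = 0.01) -> np.ndarray:
    gain = math.sqrt(2.0 / (1.0 + slope * slope))
    std = gain / math.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv(Module):
    def __init__(self, cin, cout, kernel, stride, padding,
                 rng: np.random.Generator, bias: bool = True):
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        fan_in = cin * int(np.prod(kernel))
        self.weight = Tensor(_kaiming(rng, (cout, cin) + tuple(kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x):
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)

    def out_spatial(self, spatial):
        k = self.weight.shape[2:]
        return tuple((s + 2 * p - kk) // st + 1 for s, p, kk, st
                     in zip(spatial, self.padding, k, self.stride))

    def flops(self, spatial):
        out = self.out_spatial(spatial)
        cout, cin = self.weight.shape[:2]
        k = int(np.prod(self.weight.shape[2:]))
        return 2 * cin * cout * k * int(np.prod(out)), out


class ConvTranspose(Module):
    def __init__(self, cin, cout, stride, rng: np.random.Generator):
        self.stride = tuple(stride)
        fan_in = cin * int(np.prod(stride))
        self.weight = Tensor(_kaiming(rng, (cin, cout) + tuple(stride), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x):
        return conv_transpose3d(x, self.weight, self.bias, self.stride)

    def flops(self, spatial):
        out = tuple(s * k for s, k in zip(spatial, self.stride))
        cin, cout = self.weight.shape[:2]
        k = int(np.prod(self.stride))
        return 2 * cin * cout * k * int(np.prod(spatial)), out


class InstanceNorm(Module):
    def __init__(self, channels):
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def __call__(self, x):
        return instance_norm(x, self.gamma, self.beta)

    def flops(self, spatial):
        return 0, tuple(spatial)


class ConvUnit(Module):
    """conv(3) + instance norm + leaky rectifier."""

    def __init__(self, cin, cout, stride, dims, rng, slope=0.01):
        k = (3, 3, 3) if dims == 3 else (1, 3, 3)
        p = (1, 1, 1) if dims == 3 else (0, 1, 1)
        self.slope = slope
        self.conv = Conv(cin, cout, k, stride, p, rng)
        self.norm = InstanceNorm(cout)

    def __call__(self, x):
        return self.norm(self.conv(x)).leaky_relu(self.slope)

    def flops(self, spatial):
        return self.conv.flops(spatial)

    def weight_count(self):
        return self.conv.weight.size


class BottleneckUnit(Module):
    """1x1x1 compress -> 3x3x3 (carries the stride) -> 1x1x1 restore.

    Each convolution is followed by instance norm + leaky rectifier.
    """

    def __init__(self, cin, cout, stride, compression, dims, rng, slope=0.01):
        if cin % compression:
            raise ValueError(
                f"compression {compression} does not divide input width {cin}")
        m = cin // compression
        k3 = (3, 3, 3) if dims == 3 else (1, 3, 3)
        p3 = (1, 1, 1) if dims == 3 else (0, 1, 1)
        one = (1, 1, 1)
        zero = (0, 0, 0)
        self.slope = slope
        self.cin, self.cout, self.compression = cin, cout, compression
        self.conv1 = Conv(cin, m, one, one, zero, rng)
        self.norm1 = InstanceNorm(m)
        self.conv2 = Conv(m, m, k3, stride, p3, rng)
        self.norm2 = InstanceNorm(m)
        self.conv3 = Conv(m, cout, one, one, zero, rng)
        self.norm3 = InstanceNorm(cout)

    def __call__(self, x):
        x = self.norm1(self.conv1(x)).leaky_relu(self.slope)
        x = self.norm2(self.conv2(x)).leaky_relu(self.slope)
        return self.norm3(self.conv3(x)).leaky_relu(self.slope)

    def flops(self, spatial):
        total = 0
        for c in (self.conv1, self.conv2, self.conv3):
            f, spatial = c.flops(spatial)
            total += f
        return total, spatial

    def weight_count(self):
        return (self.conv1.weight.size + self.conv2.weight.size
                + self.conv3.weight.size)


def _make_unit(cin, cout, stride, cfg: NCLNetConfig, rng):
    if cfg.use_bottleneck and cin > cfg.bottleneck_threshold:
        return BottleneckUnit(cin, cout, stride, cfg.compression, cfg.dims,
                              rng, cfg.leaky_slope)
    return ConvUnit(cin, cout, stride, cfg.dims, rng, cfg.leaky_slope)


def stage_shapes(cfg: NCLNetConfig, patch: Sequence[int]):
    """Spatial shape entering each encoder stage plus the deepest shape.

    Raises if the patch is not divisible by the cumulative strides.
    """
    shapes = [tuple(patch)]
    cur = tuple(patch)
    for s in cfg.strides3():
        if any(c % st for c, st in zip(cur, s)):
            raise ValueError(
                f"patch {tuple(patch)} not divisible by stage strides "
                f"(stuck at {cur} / {s})")
        cur = tuple(c // st for c, st in zip(cur, s))
        shapes.append(cur)
    return shapes


class Extractor(Module):
    """U-shape encoder-decoder emitting full-resolution features.

    A full-resolution stem precedes the downsampling stages; each stage
    holds two convolution units, the first carrying the stage stride.
    The decoder mirrors the encoder with non-overlapping transposed
    convolutions and concatenation skips, ending at ``widths[0]``
    channels at input resolution.
    """

    def __init__(self, cfg: NCLNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        W = cfg.widths
        strides = cfg.strides3()
        self.stem = ConvUnit(cfg.in_channels, W[0], (1, 1, 1), cfg.dims, rng,
                             cfg.leaky_slope)
        self.enc = []
        prev = W[0]
        for w, s in zip(W, strides):
            self.enc.append((_make_unit(prev, w, s, cfg, rng),
                             _make_unit(w, w, (1, 1, 1), cfg, rng)))
            prev = w
        self.dec = []
        cur = W[-1]
        for l in range(len(W) - 1, -1, -1):
            target = W[l - 1] if l >= 1 else W[0]
            up = ConvTranspose(cur, target, strides[l], rng)
            a = _make_unit(2 * target, target, (1, 1, 1), cfg, rng)
            b = _make_unit(target, target, (1, 1, 1), cfg, rng)
            self.dec.append((up, a, b))
            cur = target
        self.out_channels = W[0]

    def _children(self):
        yield self.stem
        for a, b in self.enc:
            yield a
            yield b
        for up, a, b in self.dec:
            yield up
            yield a
            yield b

    def __call__(self, x):
        f = self.stem(x)
        skips = [f]
        for a, b in self.enc:
            f = b(a(f))
            skips.append(f)
        # skips[i] is the input to stage i's stride; deepest output is f
        for (up, a, b), skip in zip(self.dec, reversed(skips[:-1])):
            f = up(f)
            f = b(a(concat([f, skip], axis=1)))
        return f

    def flops(self, spatial):
        total, sp = self.stem.flops(spatial)
        enc_spatials = []
        for a, b in self.enc:
            enc_spatials.append(sp)
            f, sp = a.flops(sp)
            total += f
            f, sp = b.flops(sp)
            total += f
        for (up, a, b), _ in zip(self.dec, reversed(enc_spatials)):
            f, sp = up.flops(sp)
            total += f
            f, sp = a.flops(sp)
            total += f
            f, sp = b.flops(sp)
            total += f
        return total, sp


class FusionModule(Module):
    """Multi-phase spatial attention fusion.

    Concatenated branch features pass through a hidden convolution unit;
    two single-channel score maps follow, normalized across the two
    phases by a two-way softmax; the attention-weighted feature sum is
    refined by one convolution unit.
    """

    def __init__(self, width, hidden, dims, rng, slope=0.01):
        k = (3, 3, 3) if dims == 3 else (1, 3, 3)
        p = (1, 1, 1) if dims == 3 else (0, 1, 1)
        self.stemunit = ConvUnit(2 * width, hidden, (1, 1, 1), dims, rng, slope)
        self.score_n = Conv(hidden, 1, k, (1, 1, 1), p, rng)
        self.score_c = Conv(hidden, 1, k, (1, 1, 1), p, rng)
        self.post = ConvUnit(width, width, (1, 1, 1), dims, rng, slope)

    def __call__(self, f_n, f_c):
        h = self.stemunit(concat([f_n, f_c], axis=1))
        a_n = (self.score_n(h) - self.score_c(h)).sigmoid()
        fused = a_n * f_n + (1.0 - a_n) * f_c
        return self.post(fused)

    def flops(self, spatial):
        total, _ = self.stemunit.flops(spatial)
        for c in (self.score_n, self.score_c):
            f, _ = c.flops(spatial)
            total += f
        f, _ = self.post.flops(spatial)
        return total + f, spatial


class NCLNet(Module):
    """Two-branch (or single-extractor) segmentation model.

    Calling conventions: two-branch models take ``(nect, cect)``
    patches; single-extractor models take one patch.  Inputs are
    ``(N, 1, D, H, W)`` arrays or Tensors; outputs are sigmoid
    probability maps at input resolution.
    """

    def __init__(self, cfg: NCLNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        one, zero = (1, 1, 1), (0, 0, 0)
        if cfg.two_branch:
            self.branch_n = Extractor(cfg, rng)
            self.branch_c = Extractor(cfg, rng)
            self.fusion = FusionModule(cfg.widths[0], cfg.fusion_hidden,
                                       cfg.dims, rng, cfg.leaky_slope)
            self.head_ne = Conv(cfg.widths[0], 1, one, one, zero, rng)
            self.head_ce = Conv(cfg.widths[0], 1, one, one, zero, rng)
            self.head_fuse = Conv(cfg.widths[0], 1, one, one, zero, rng)
        else:
            self.branch = Extractor(cfg, rng)
            self.head = Conv(cfg.widths[0], 1, one, one, zero, rng)

    def __call__(self, x_n, x_c=None) -> PredictionTriplet:
        if self.cfg.two_branch:
            if x_c is None:
                raise ValueError("two-branch model needs both phase patches")
            xn = x_n if isinstance(x_n, Tensor) else Tensor(x_n)
            xc = x_c if isinstance(x_c, Tensor) else Tensor(x_c)
            if xn.shape != xc.shape:
                raise ValueError(
                    f"phase patches differ in shape: {xn.shape} vs {xc.shape}")
            f_n = self.branch_n(xn)
            f_c = self.branch_c(xc)
            return PredictionTriplet(
                p_ne=self.head_ne(f_n).sigmoid(),
                p_ce=self.head_ce(f_c).sigmoid(),
                p_fuse=self.head_fuse(self.fusion(f_n, f_c)).sigmoid(),
            )
        x = x_n if isinstance(x_n, Tensor) else Tensor(x_n)
        return PredictionTriplet(p_fuse=self.head(self.branch(x)).sigmoid())

    def flops(self, spatial):
        if self.cfg.two_branch:
            total = 0
            for br in (self.branch_n, self.branch_c):
                f, sp = br.flops(spatial)
                total += f
            f, _ = self.fusion.flops(spatial)
            total += f
            for h in (self.head_ne, self.head_ce, self.head_fuse):
                f, _ = h.flops(spatial)
                total += f
            return total
        f, sp = self.branch.flops(spatial)
        return f + self.head.flops(spatial)[0]


def build_extractor(cfg: NCLNetConfig, seed: int = 0) -> Extractor:
    return Extractor(cfg, np.random.default_rng(seed))


def build_nclnet(cfg: NCLNetConfig, seed: int = 0) -> NCLNet:
    """Instantiate the model with seeded Kaiming initialization."""
    return NCLNet(cfg, np.random.default_rng(seed))


def count_parameters(model: Module) -> int:
    """Total trainable weight and bias elements of a built model."""
    return int(sum(p.size for p in model.parameters()))


def count_flops(model: NCLNet, patch: Sequence[int]) -> int:
    """Deterministic FLOP count for one forward pass at ``patch`` shape.

    Convention: 2 FLOPs per convolution multiply-accumulate; bias,
    normalization and activation arithmetic are excluded.
    """
    if model.cfg.two_branch:
        stage_shapes(model.cfg, patch)  # validates divisibility
    return int(model.flops(tuple(patch)))
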