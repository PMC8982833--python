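"""The three 3D U-Net variants: guided teacher, SO student, DO student.

All share the same building blocks: two 3x3x3 convolutions per level,
each followed by instance normalization and PReLU; downsampling by
3D convolutions with stride two (no pooling); upsampling by stride-2
transposed convolutions; skip connections by channel concatenation; a
1x1x1 sigmoid head per output.  Channel widths double per level.

The guided teacher has three downsamplings and two input channels (image
+ guidance); the students have four downsamplings and a single input
channel.  The dual-output (DO) student adds a second decoder branch —
sharing the encoder and its skip connections — whose head approximates
the axial bounding box of the tumor to sharpen localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "NetConfig",
    "SegNet",
    "build_teacher",
    "build_student",
    "forward",
    "teacher_config",
    "student_config",
]


@dataclass
class NetConfig:
    levels: int = 4  # number of downsampling steps
    base_width: int = 16
    in_channels: int = 1
    out_heads: int = 1

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.out_heads not in (1, 2):
            raise ValueError("out_heads must be 1 or 2")

    @property
    def divisor(self) -> int:
        """Input spatial dims must divide 2^levels."""
        return 2**self.levels


def teacher_config(base_width: int = 16, guided: bool = True) -> NetConfig:
    return NetConfig(levels=3, base_width=base_width, in_channels=2 if guided else 1)


def student_config(base_width: int = 16, dual: bool = False) -> NetConfig:
    return NetConfig(levels=4, base_width=base_width, in_channels=1,
                     out_heads=2 if dual else 1)


# ---------------------------------------------------------------------------
# Parameter initialization


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv:
    def __init__(self, rng, ci, co, k, stride=1, pad=1):
        self.w = Tensor(_he(rng, (co, ci, k, k, k), ci * k**3), requires_grad=True)
        self.b = Tensor(np.zeros(co, np.float32), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return ag.conv3d(x, self.w, self.b, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class _ConvT(_Conv):
    def __init__(self, rng, ci, co):
        self.w = Tensor(_he(rng, (ci, co, 2, 2, 2), ci * 8), requires_grad=True)
        self.b = Tensor(np.zeros(co, np.float32), requires_grad=True)

    def __call__(self, x):
        return ag.conv_transpose3d(x, self.w, self.b)


class _PReLU:
    def __init__(self, co, init=0.25):
        self.a = Tensor(np.full(co, init, np.float32), requires_grad=True)

    def __call__(self, x):
        return ag.prelu(x, self.a)

    def params(self):
        return [self.a]


class _Block:
    """conv -> IN -> PReLU, twice."""

    def __init__(self, rng, ci, co):
        self.c1 = _Conv(rng, ci, co, 3)
        self.p1 = _PReLU(co)
        self.c2 = _Conv(rng, co, co, 3)
        self.p2 = _PReLU(co)

    def __call__(self, x):
        x = self.p1(ag.instance_norm(self.c1(x)))
        return self.p2(ag.instance_norm(self.c2(x)))

    def params(self):
        return self.c1.params() + self.p1.params() + self.c2.params() + self.p2.params()


class _Down:
    """Stride-2 3x3x3 convolution doubling the channel count."""

    def __init__(self, rng, ci, co):
        self.c = _Conv(rng, ci, co, 3, stride=2)
        self.p = _PReLU(co)

    def __call__(self, x):
        return self.p(ag.instance_norm(self.c(x)))

    def params(self):
        return self.c.params() + self.p.params()


class _Decoder:
    def __init__(self, rng, widths):
        # widths: encoder widths per level, shallow -> deep (len = levels + 1)
        self.ups = []
        self.blocks = []
        for lvl in range(len(widths) - 1, 0, -1):
            self.ups.append(_ConvT(rng, widths[lvl], widths[lvl - 1]))
            self.blocks.append(_Block(rng, 2 * widths[lvl - 1], widths[lvl - 1]))

    def __call__(self, bottom, skips):
        x = bottom
        for up, blk, skip in zip(self.ups, self.blocks, reversed(skips)):
            x = blk(ag.concat(up(x), skip))
        return x

    def params(self):
        out = []
        for up, blk in zip(self.ups, self.blocks):
            out += up.params() + blk.params()
        return out


class SegNet:
    """A U-Net with a shared encoder and one or two decoder branches."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.base_width
        self.widths = [w * 2**lvl for lvl in range(cfg.levels + 1)]
        self.stem = _Block(rng, cfg.in_channels, self.widths[0])
        self.downs = [
            _Down(rng, self.widths[lvl], self.widths[lvl + 1]) for lvl in range(cfg.levels)
        ]
        self.enc_blocks = [
            _Block(rng, self.widths[lvl + 1], self.widths[lvl + 1])
            for lvl in range(cfg.levels)
        ]
        self.decoders = [_Decoder(rng, self.widths) for _ in range(cfg.out_heads)]
        self.heads = [_Conv(rng, self.widths[0], 1, 1, pad=0) for _ in range(cfg.out_heads)]

    # -- introspection -----------------------------------------------------

    def encoder_params(self) -> list[Tensor]:
        out = self.stem.params()
        for d, b in zip(self.downs, self.enc_blocks):
            out += d.params() + b.params()
        return out

    def params(self) -> list[Tensor]:
        out = self.encoder_params()
        for dec, head in zip(self.decoders, self.heads):
            out += dec.params() + head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def bottleneck_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        f = 2**self.cfg.levels
        return tuple(s // f for s in spatial)

    def check_input(self, shape) -> None:
        if len(shape) != 4:
            raise ValueError(f"expected (C, D, H, W) input, got shape {shape}")
        if shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"network expects {self.cfg.in_channels} input channel(s), got {shape[0]}"
            )
        f = 2**self.cfg.levels
        bad = [s for s in shape[1:] if s % f or s < f]
        if bad:
            raise ValueError(
                f"spatial dims {shape[1:]} must be positive multiples of 2^levels = {f}"
            )

    # -- forward -----------------------------------------------------------

    def forward_t(self, x: Tensor) -> list[Tensor]:
        """Graph-building forward; returns one probability Tensor per head."""
        self.check_input(x.data.shape)
        skips = []
        h = self.stem(x)
        for down, blk in zip(self.downs, self.enc_blocks):
            skips.append(h)
            h = blk(down(h))
        outs = []
        for dec, head in zip(self.decoders, self.heads):
            outs.append(ag.sigmoid(head(dec(h, skips))))
        return outs

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference: (C, D, H, W) -> (heads, D, H, W) probabilities."""
        outs = self.forward_t(Tensor(np.asarray(batch, dtype=np.float32)))
        return np.concatenate([o.data for o in outs], axis=0)

    # -- (de)serialization --------------------------------------------------

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError(f"state has {len(arrays)} arrays, network has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32).copy()


def build_teacher(cfg: NetConfig, seed: int = 0) -> SegNet:
    """Guided teacher: 3 downsamplings, image + guidance input, one head."""
    if cfg.levels != 3:
        raise ValueError("teacher has three downsamplings (levels=3)")
    if cfg.out_heads != 1:
        raise ValueError("teacher has a single output head")
    return SegNet(cfg, seed=seed)


def build_student(cfg: NetConfig, dual: bool | None = None, seed: int = 0) -> SegNet:
    """Student: 4 downsamplings, image-only input; dual adds the box head."""
    if dual is not None and cfg.out_heads != (2 if dual else 1):
        cfg = NetConfig(cfg.levels, cfg.base_width, cfg.in_channels, 2 if dual else 1)
    if cfg.levels != 4:
        raise ValueError("student has four downsamplings (levels=4)")
    if cfg.in_channels != 1:
        raise ValueError("student takes the image only (in_channels=1)")
    return SegNet(cfg, seed=seed)


def forward(net: SegNet, batch: np.ndarray) -> np.ndarray:
    """Deterministic inference wrapper: (C, D, H, W) -> (heads, D, H, W)."""
    return net.predict(batch)
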