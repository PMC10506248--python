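"""The four segmentation architectures.

All nets share one contract: a single-channel preprocessed grid goes in, a
same-sized sigmoid probability map comes out. Channel widths per resolution
level default to [16, 32, 64, 128, 256]; downsampling is 2x2 max pooling and
every convolution uses zero padding, batch normalization before ReLU, and a
final 1x1 convolution + sigmoid head.

Topologies
----------
``resunet``
    U-shaped encoder/decoder with residual blocks; skips are additive, the
    decoder upsamples with learned 2x2 transposed convolutions projecting to
    the skip width. The residual blocks of this net use a single conv-BN
    path; that layout reproduces the reference 0.81 M parameter budget at the
    default widths.
``unetpp``
    The nested dense-skip topology: node (i, j) receives the concatenation of
    all previous nodes on its row plus the bilinearly upsampled node
    (i+1, j-1), and applies two conv3x3-BN-ReLU layers. 2.29 M parameters at
    the default widths.
``ghost_unet``
    The plain U topology with every conv block replaced by a ghost
    bottleneck; concat skips, bilinear upsampling.
``ghost_unetpp``
    The nested topology with one ghost bottleneck per node: 15 bottlenecks at
    5 levels (5+4+3+2+1). 0.35 M parameters at the default widths.

Ghost modules generate ceil(out/s) "intrinsic" channels with a primary 1x1
convolution and the remaining channels with a cheap depthwise 3x3
convolution applied to intrinsic maps, then concatenate; a bottleneck stacks
an expanding and a projecting ghost module around a residual shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .ndnn import autograd as ag
from .ndnn.autograd import Tensor
from .ndnn.nn import (BatchNorm2d, Conv2d, DepthwiseConv2d, Module, ModuleList,
                      TransposedConv2x2)
from .types import BinaryMask

ARCH_NAMES = ("resunet", "unetpp", "ghost_unet", "ghost_unetpp")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualBlockCfg:
    in_channels: int
    out_channels: int
    n_convs: int = 2          # conv-BN(-ReLU-conv-BN) path length
    projection_shortcut: bool | None = None  # None: project iff channels differ


@dataclass(frozen=True)
class GhostModuleCfg:
    in_channels: int
    out_channels: int
    ratio: int = 2            # s; intrinsic = ceil(out / s)
    primary_kernel: int = 1
    cheap_kernel: int = 3

    @property
    def intrinsic_channels(self) -> int:
        return math.ceil(self.out_channels / self.ratio)

    @property
    def ghost_channels(self) -> int:
        return self.out_channels - self.intrinsic_channels


@dataclass(frozen=True)
class GhostBottleneckCfg:
    in_channels: int
    out_channels: int
    expansion: float = 1.5    # width of the hidden (expanded) ghost module
    ratio: int = 2


@dataclass(frozen=True)
class ArchitectureCfg:
    name: str
    widths: Tuple[int, ...] = (16, 32, 64, 128, 256)
    input_size: Tuple[int, int] = (512, 512)
    batch_norm_before_relu: bool = True   # fixed by the uniform protocol
    zero_padding: bool = True             # fixed by the uniform protocol
    ghost_ratio: int = 2
    ghost_expansion: float = 1.5
    light_decoder: bool = False           # ghost_unet only: halved decoder widths

    def __post_init__(self):
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}; expected one of {ARCH_NAMES}")
        if len(self.widths) < 2:
            raise ValueError("need at least two resolution levels")
        stride = 2 ** (len(self.widths) - 1)
        h, w = self.input_size
        if h % stride or w % stride:
            raise ValueError(f"input size {self.input_size} not divisible by {stride} "
                             f"({len(self.widths)} levels)")

    @property
    def levels(self) -> int:
        return len(self.widths)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBNReLU(Module):
    def __init__(self, cin: int, cout: int, k: int, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class VGGBlock(Module):
    """Two conv3x3-BN-ReLU layers (the UNET++ node body)."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.c1 = ConvBNReLU(cin, cout, 3, rng)
        self.c2 = ConvBNReLU(cout, cout, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x))


class ResidualBlock(Module):
    """z = F(x) + W_s x with ReLU after the addition.

    F is conv3x3-BN (n_convs=1) or conv3x3-BN-ReLU-conv3x3-BN (n_convs=2);
    W_s is the identity when channel counts match, else a learned 1x1
    projection.
    """

    def __init__(self, cfg: ResidualBlockCfg, rng):
        super().__init__()
        self.cfg = cfg
        cin, cout = cfg.in_channels, cfg.out_channels
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        if cfg.n_convs == 2:
            self.conv2 = Conv2d(cout, cout, 3, rng)
            self.bn2 = BatchNorm2d(cout)
        elif cfg.n_convs != 1:
            raise ValueError("n_convs must be 1 or 2")
        project = cfg.projection_shortcut
        if project is None:
            project = cin != cout
        if project:
            self.shortcut = Conv2d(cin, cout, 1, rng)
        elif cin != cout:
            raise ValueError("identity shortcut requires matching channels")
        else:
            self.shortcut = None

    def forward(self, x):
        h = self.bn1(self.conv1(x))
        if self.cfg.n_convs == 2:
            h = self.bn2(self.conv2(ag.relu(h)))
        s = x if self.shortcut is None else self.shortcut(x)
        return ag.relu(ag.add(h, s))


class GhostModule(Module):
    """Primary conv makes intrinsic maps; a cheap depthwise conv ghosts them."""

    def __init__(self, cfg: GhostModuleCfg, rng, relu: bool = True):
        super().__init__()
        self.cfg = cfg
        self.relu = relu
        self.primary = Conv2d(cfg.in_channels, cfg.intrinsic_channels, cfg.primary_kernel, rng)
        self.bn_primary = BatchNorm2d(cfg.intrinsic_channels)
        if cfg.ghost_channels:
            if cfg.ghost_channels > cfg.intrinsic_channels:
                raise ValueError("ghost channels cannot exceed intrinsic channels (ratio s=2 max here)")
            self.cheap = DepthwiseConv2d(cfg.ghost_channels, cfg.cheap_kernel, rng)
            self.bn_cheap = BatchNorm2d(cfg.ghost_channels)
        else:
            self.cheap = None

    def forward(self, x):
        if x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(f"ghost module expected {self.cfg.in_channels} channels, "
                             f"got {x.data.shape[1]}")
        intrinsic = self.bn_primary(self.primary(x))
        if self.relu:
            intrinsic = ag.relu(intrinsic)
        if self.cheap is None:
            return intrinsic
        src = intrinsic
        if self.cfg.ghost_channels != self.cfg.intrinsic_channels:
            src = _channel_slice(intrinsic, 0, self.cfg.ghost_channels)
        ghost = self.bn_cheap(self.cheap(src))
        if self.relu:
            ghost = ag.relu(ghost)
        return ag.concat([intrinsic, ghost], axis=1)


def _channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    out_data = x.data[:, start:stop]

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, start:stop] = g
        x._accumulate(full)

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, _parents=(x,) if req else (),
                  _backward=backward if req else None)


class GhostBottleneck(Module):
    """Expanding ghost module, projecting ghost module, residual shortcut."""

    def __init__(self, cfg: GhostBottleneckCfg, rng):
        super().__init__()
        self.cfg = cfg
        mid = int(round(cfg.expansion * cfg.out_channels))
        self.ghost1 = GhostModule(GhostModuleCfg(cfg.in_channels, mid, cfg.ratio), rng, relu=True)
        self.ghost2 = GhostModule(GhostModuleCfg(mid, cfg.out_channels, cfg.ratio), rng, relu=False)
        if cfg.in_channels != cfg.out_channels:
            self.shortcut = Conv2d(cfg.in_channels, cfg.out_channels, 1, rng)
        else:
            self.shortcut = None

    def forward(self, x):
        h = self.ghost2(self.ghost1(x))
        s = x if self.shortcut is None else self.shortcut(x)
        return ag.relu(ag.add(h, s))


# ---------------------------------------------------------------------------
# whole nets
# ---------------------------------------------------------------------------

class _SegNet(Module):
    """Shared plumbing: config echo, ndarray predict(), divisibility checks."""

    def __init__(self, cfg: ArchitectureCfg):
        super().__init__()
        self.cfg = cfg

    def _check_input(self, x: Tensor) -> None:
        stride = 2 ** (self.cfg.levels - 1)
        n, c, h, w = x.data.shape
        if c != 1:
            raise ValueError(f"expected single-channel input, got {c} channels")
        if h % stride or w % stride:
            raise ValueError(f"spatial dims ({h}, {w}) must be divisible by {stride}")

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one preprocessed (H, W) grid, in eval mode."""
        was_training = self.training
        self.eval()
        try:
            x = Tensor(np.asarray(image, dtype=np.float32)[None, None])
            out = self.forward(x)
        finally:
            if was_training:
                self.train()
        return out.data[0, 0]


class ResUNet(_SegNet):
    def __init__(self, cfg: ArchitectureCfg, rng):
        super().__init__(cfg)
        w = cfg.widths
        self.encoder = ModuleList()
        prev = 1
        for width in w:
            self.encoder.append(ResidualBlock(ResidualBlockCfg(prev, width, n_convs=1), rng))
            prev = width
        self.ups = ModuleList()
        self.decoder = ModuleList()
        for i in range(cfg.levels - 2, -1, -1):
            self.ups.append(TransposedConv2x2(w[i + 1], w[i], rng))
            self.decoder.append(ResidualBlock(ResidualBlockCfg(w[i], w[i], n_convs=1), rng))
        self.head = Conv2d(w[0], 1, 1, rng)

    def forward(self, x):
        self._check_input(x)
        skips = []
        for i, block in enumerate(self.encoder):
            if i:
                x = ag.maxpool2x2(x)
            x = block(x)
            skips.append(x)
        y = skips[-1]
        for up, block, skip in zip(self.ups, self.decoder, reversed(skips[:-1])):
            y = block(ag.add(up(y), skip))
        return ag.sigmoid(self.head(y))


class _NestedNet(_SegNet):
    """UNET++ wiring shared by the plain and ghost variants."""

    def __init__(self, cfg: ArchitectureCfg, rng, make_block):
        super().__init__(cfg)
        w = cfg.widths
        L = cfg.levels
        self.nodes = ModuleList()
        self._index = {}
        for i in range(L):
            cin = 1 if i == 0 else w[i - 1]
            self._index[(i, 0)] = len(self.nodes)
            self.nodes.append(make_block(cin, w[i], rng))
        for i in range(L - 1):
            for j in range(1, L - i):
                cin = w[i] * j + w[i + 1]
                self._index[(i, j)] = len(self.nodes)
                self.nodes.append(make_block(cin, w[i], rng))
        self.head = Conv2d(w[0], 1, 1, rng)

    def forward(self, x):
        self._check_input(x)
        L = self.cfg.levels
        outs = {}
        for i in range(L):
            inp = x if i == 0 else ag.maxpool2x2(outs[(i - 1, 0)])
            outs[(i, 0)] = self.nodes[self._index[(i, 0)]](inp)
        for j in range(1, L):
            for i in range(L - j):
                parts = [outs[(i, jj)] for jj in range(j)]
                parts.append(ag.upsample_bilinear2x(outs[(i + 1, j - 1)]))
                outs[(i, j)] = self.nodes[self._index[(i, j)]](ag.concat(parts, axis=1))
        return ag.sigmoid(self.head(outs[(0, L - 1)]))


class UNetPP(_NestedNet):
    def __init__(self, cfg: ArchitectureCfg, rng):
        super().__init__(cfg, rng, lambda cin, cout, r: VGGBlock(cin, cout, r))


class GhostUNetPP(_NestedNet):
    def __init__(self, cfg: ArchitectureCfg, rng):
        def make(cin, cout, r):
            return GhostBottleneck(
                GhostBottleneckCfg(cin, cout, cfg.ghost_expansion, cfg.ghost_ratio), r)
        super().__init__(cfg, rng, make)

    @property
    def num_bottlenecks(self) -> int:
        return len(self.nodes)


class GhostUNet(_SegNet):
    def __init__(self, cfg: ArchitectureCfg, rng):
        super().__init__(cfg)
        w = cfg.widths

        def gb(cin, cout):
            return GhostBottleneck(
                GhostBottleneckCfg(cin, cout, cfg.ghost_expansion, cfg.ghost_ratio), rng)

        self.encoder = ModuleList()
        prev = 1
        for width in w:
            self.encoder.append(gb(prev, width))
            prev = width
        dec_w = [max(1, width // 2) if cfg.light_decoder else width for width in w[:-1]]
        self.decoder = ModuleList()
        prev = w[-1]
        for i in range(cfg.levels - 2, -1, -1):
            self.decoder.append(gb(prev + w[i], dec_w[i]))
            prev = dec_w[i]
        self.head = Conv2d(dec_w[0], 1, 1, rng)

    def forward(self, x):
        self._check_input(x)
        skips = []
        for i, block in enumerate(self.encoder):
            if i:
                x = ag.maxpool2x2(x)
            x = block(x)
            skips.append(x)
        y = skips[-1]
        for block, skip in zip(self.decoder, reversed(skips[:-1])):
            y = block(ag.concat([ag.upsample_bilinear2x(y), skip], axis=1))
        return ag.sigmoid(self.head(y))


_BUILDERS = {
    "resunet": ResUNet,
    "unetpp": UNetPP,
    "ghost_unet": GhostUNet,
    "ghost_unetpp": GhostUNetPP,
}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_model(cfg: ArchitectureCfg, seed: int = 0) -> _SegNet:
    """Build and deterministically initialize the named architecture."""
    rng = np.random.default_rng(seed)
    model = _BUILDERS[cfg.name](cfg, rng)
    model.eval()
    return model


def forward(model: _SegNet, x: np.ndarray) -> np.ndarray:
    """Probability map for a preprocessed (H, W) grid (eval mode)."""
    return model.predict(x)


def count_trainable_parameters(model: Module) -> int:
    """Exact count of learnable scalars (conv weights/biases, BN affine)."""
    return model.num_parameters()


def binarize(prob: np.ndarray, threshold: float = 0.5, label: str = "prediction") -> BinaryMask:
    """Threshold a probability map into a mask (p >= threshold counts as 1)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob = np.asarray(prob)
    return BinaryMask(prob >= threshold, label=label)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: _SegNet, path) -> None:
    """Write parameters + BN statistics as ``.npz`` with a JSON config sidecar."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **model.state_arrays())
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = dataclasses.asdict(model.cfg)
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_model(path) -> _SegNet:
    """Rebuild a model from :func:`save_model` output."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    raw = json.loads(sidecar.read_text())
    raw["widths"] = tuple(raw["widths"])
    raw["input_size"] = tuple(raw["input_size"])
    model = build_model(ArchitectureCfg(**raw), seed=0)
    with np.load(path) as data:
        model.load_state_arrays(dict(data))
    return model
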