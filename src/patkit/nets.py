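"""HD-UNet and baseline architectures for 128x128 PAT image restoration.

Four image-to-image variants share one U-shaped skeleton of ``levels``
resolution levels (default 4, i.e. three down/up transitions):

* ``hd``      -- hybrid dense: encoder dense blocks split each growth step
                 into half standard (dilation 1) and half dilated (dilation
                 2) filters; decoder dense blocks are all-standard; a
                 residual block bridges the bottleneck.
* ``fd``      -- fully dense: standard dense blocks in both paths.
* ``dd``      -- dense dilated: each dense step learns the full growth at
                 dilation 1 *and* at dilation 2 (concatenated), in both
                 paths -- the parameter-hungry design the hybrid split
                 economizes on.
* ``vanilla`` -- plain double-convolution U-Net blocks.

At level ``l`` the feature target is ``fl = 2^(l-1) * fi`` and the dense
growth rate ``kl = 2^(l-1) * 8``; every dense block runs ``fi/8`` growth
steps so standard/split blocks emit exactly ``fl`` new channels (input plus
block output = 2*fl).  Down-transitions are a 1x1 convolution block followed
by a 3x3 stride-2 convolution block; up-transitions are 3x3 stride-2
transposed convolution blocks; every convolution block is
convolution -> batch norm -> ReLU.  The head is two 3x3 convolutions, the
final one ReLU-activated without batch norm so outputs stay in the
target range [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import (
    Module,
    Sequential,
    Conv2d,
    ReLU,
    conv_block,
    transposed_conv_block,
)

__all__ = [
    "NetConfig",
    "UNet",
    "DenseBlock",
    "build_network",
    "count_parameters",
    "receptive_field",
]

VARIANTS = ("hd", "fd", "dd", "vanilla")


@dataclass(frozen=True)
class NetConfig:
    """Hyper-structure of the network family.

    ``fi`` is the initial feature count (never published for this family;
    32 by default, 16 for desk-scale experiments) and must be divisible by
    ``growth_base`` so each dense block runs an integral number of steps.
    ``max_dilation`` caps the dilation rate (2 by default, to limit gridding
    artifacts); setting it to 1 disables dilation everywhere.
    """

    variant: str = "hd"
    levels: int = 4
    fi: int = 32
    growth_base: int = 8
    max_dilation: int = 2
    strict_shape: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.fi % self.growth_base != 0:
            raise ValueError("fi must be divisible by growth_base")
        if self.levels < 2:
            raise ValueError("need at least two levels")
        if self.max_dilation < 1:
            raise ValueError("max_dilation must be >= 1")

    def fl(self, level: int) -> int:
        """Feature target at a level: fl = 2^(l-1) * fi."""
        return 2 ** (level - 1) * self.fi

    def kl(self, level: int) -> int:
        """Dense growth rate at a level: kl = 2^(l-1) * growth_base."""
        return 2 ** (level - 1) * self.growth_base

    @property
    def steps(self) -> int:
        """Growth steps per dense block (fi / growth_base)."""
        return self.fi // self.growth_base

    def dilated_split(self, level: int) -> tuple[int, int]:
        """Equal standard/dilated halves of kl for hybrid encoder steps."""
        k = self.kl(level)
        return k // 2, k - k // 2


class DenseBlock(Module):
    """Iterative dense block: each step consumes the concatenation of the
    input and all previous step outputs and adds new channels.

    ``mode``: ``standard`` (one dilation-1 conv of ``growth`` filters per
    step), ``split`` (growth/2 at dilation 1 + growth/2 at ``dilation``),
    ``dual`` (full growth at each of the two rates, doubling the growth).
    """

    def __init__(self, cin: int, steps: int, growth: int, mode: str,
                 rng: np.random.Generator, dilation: int = 2):
        super().__init__()
        if mode not in ("standard", "split", "dual"):
            raise ValueError(f"unknown dense mode {mode!r}")
        self.mode = mode
        self.step_convs: list[list[Sequential]] = []
        self.step_specs: list[list[tuple[int, int]]] = []  # (channels, dilation)
        c = cin
        for _ in range(steps):
            if mode == "standard":
                convs = [conv_block(c, growth, 3, rng)]
                spec = [(growth, 1)]
            elif mode == "split":
                half_s, half_d = growth // 2, growth - growth // 2
                convs = [
                    conv_block(c, half_s, 3, rng),
                    conv_block(c, half_d, 3, rng, dilation=dilation),
                ]
                spec = [(half_s, 1), (half_d, dilation)]
            else:  # dual
                convs = [
                    conv_block(c, growth, 3, rng),
                    conv_block(c, growth, 3, rng, dilation=dilation),
                ]
                spec = [(growth, 1), (growth, dilation)]
            self.step_convs.append(convs)
            self.step_specs.append(spec)
            c += sum(ch for ch, _ in spec)
        self.cin = cin
        self.out_channels = c
        self._flat = [m for step in self.step_convs for m in step]  # for parameters()

    def _children(self):
        yield from self._flat

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = x
        self._in_channels = []
        for convs in self.step_convs:
            self._in_channels.append(feats.shape[1])
            outs = [m(feats) for m in convs]
            feats = np.concatenate([feats] + outs, axis=1)
        return feats

    def backward(self, dfeats: np.ndarray) -> np.ndarray:
        for convs, spec, c_in in zip(
            reversed(self.step_convs), reversed(self.step_specs), reversed(self._in_channels)
        ):
            off = c_in
            dx = dfeats[:, :c_in].copy()
            for m, (ch, _) in zip(convs, spec):
                dx += m.backward(np.ascontiguousarray(dfeats[:, off : off + ch]))
                off += ch
            dfeats = dx
        return dfeats


class VanillaBlock(Sequential):
    """Two plain 3x3 convolution blocks (classic U-Net level)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__(conv_block(cin, cout, 3, rng), conv_block(cout, cout, 3, rng))
        self.out_channels = cout


class ResidualBridge(Module):
    """Two 3x3 convolution blocks at the bottleneck's feature-target width,
    with an identity shortcut (1x1 projection when the widths differ)."""

    def __init__(self, cin: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.main = Sequential(conv_block(cin, width, 3, rng), conv_block(width, width, 3, rng))
        self.proj = Conv2d(cin, width, 1, rng) if cin != width else None
        self.out_channels = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        short = x if self.proj is None else self.proj(x)
        return self.main(x) + short

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dshort = dy if self.proj is None else self.proj.backward(dy)
        return self.main.backward(dy) + dshort


class _Concat:
    """Channel concatenation bookkeeping for skip connections."""

    @staticmethod
    def forward(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.concatenate([a, b], axis=1)

    @staticmethod
    def backward(dy: np.ndarray, ca: int) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.ascontiguousarray(dy[:, :ca]),
            np.ascontiguousarray(dy[:, ca:]),
        )


class UNet(Module):
    """U-shaped image-to-image network; see the module docstring."""

    def __init__(self, config: NetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.levels
        dense = config.variant != "vanilla"
        enc_mode = {"hd": "split", "fd": "standard", "dd": "dual"}.get(config.variant)
        dec_mode = {"hd": "standard", "fd": "standard", "dd": "dual"}.get(config.variant)
        dil = config.max_dilation

        def make_block(cin, level, mode):
            if mode is None:
                return VanillaBlock(cin, config.fl(level), rng)
            return DenseBlock(cin, config.steps, config.kl(level), mode, rng, dilation=dil)

        self.stem = conv_block(1, config.fi, 3, rng) if dense else None
        self.enc_blocks: list[Module] = []
        self.downs: list[Sequential] = []
        cur = config.fi if dense else 1
        for l in range(1, L):
            if not dense:
                block = make_block(cur, l, None)
            else:
                block = make_block(config.fl(l), l, enc_mode)
            self.enc_blocks.append(block)
            nxt = config.fl(l + 1)
            self.downs.append(
                Sequential(
                    conv_block(block.out_channels, nxt, 1, rng),
                    conv_block(nxt, nxt, 3, rng, stride=2),
                )
            )
            cur = nxt
        self.bottleneck = make_block(cur, L, enc_mode)
        cur = self.bottleneck.out_channels
        if config.variant == "hd":
            self.bridge = ResidualBridge(cur, config.fl(L), rng)
            cur = self.bridge.out_channels
        else:
            self.bridge = None

        self.ups: list[Sequential] = []
        self.dec_blocks: list[Module] = []
        for l in range(L - 1, 0, -1):
            fl = config.fl(l)
            self.ups.append(transposed_conv_block(cur, fl, rng))
            if dense:
                block = Sequential(
                    conv_block(2 * fl, fl, 1, rng),
                    DenseBlock(fl, config.steps, config.kl(l), dec_mode, rng, dilation=dil),
                )
                block.out_channels = block.mods[1].out_channels
            else:
                block = VanillaBlock(2 * fl, fl, rng)
            self.dec_blocks.append(block)
            cur = block.out_channels

        self.head = Sequential(
            conv_block(cur, config.fi, 3, rng),
            Conv2d(config.fi, 1, 3, rng),
            ReLU(),
        )
        self.last_channels: dict[str, list[int]] = {}

    # -- shape contract ----------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expect input of shape (N, 1, H, W)")
        h, w = x.shape[2:]
        if self.config.strict_shape and (h, w) != (128, 128):
            raise ValueError("strict shape mode requires 128x128 inputs")
        div = 2 ** (self.config.levels - 1)
        if h % div or w % div:
            raise ValueError(f"input size must be divisible by {div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        dense = self.stem is not None
        rec = self.last_channels = {"enc_block_out": [], "down_out": [], "dec_block_out": []}
        h = self.stem(x.astype(np.float32, copy=False)) if dense else x.astype(np.float32)
        skips = []
        for block, down in zip(self.enc_blocks, self.downs):
            if dense:
                skips.append(h)
            h = block(h)
            rec["enc_block_out"].append(h.shape[1])
            if not dense:
                skips.append(h)
            h = down(h)
            rec["down_out"].append(h.shape[1])
        h = self.bottleneck(h)
        if self.bridge is not None:
            h = self.bridge(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up(h)
            h = _Concat.forward(h, skip)
            h = block(h)
            rec["dec_block_out"].append(h.shape[1])
        return self.head(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dense = self.stem is not None
        dy = self.head.backward(dy.astype(np.float32, copy=False))
        dskips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec_blocks)):
            dy = block.backward(dy)
            ca = dy.shape[1] - self._skip_channels[len(dskips)]
            dy, dskip = _Concat.backward(dy, ca)
            dskips.append(dskip)  # collected in encoder level order 1..L-1
            dy = up.backward(dy)
        if self.bridge is not None:
            dy = self.bridge.backward(dy)
        dy = self.bottleneck.backward(dy)
        for block, down, dskip in zip(
            reversed(self.enc_blocks), reversed(self.downs), reversed(dskips)
        ):
            dy = down.backward(dy)
            if self.stem is None:
                dy = dy + dskip
                dy = block.backward(dy)
            else:
                dy = block.backward(dy)
                dy = dy + dskip
        if dense:
            dy = self.stem.backward(dy)
        return dy


def build_network(config: NetConfig) -> UNet:
    """Construct the configured variant (deterministic for a fixed seed)."""
    return UNet(config)


def count_parameters(network: Module) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.data.size for p in network.parameters()))


def receptive_field(config: NetConfig) -> int:
    """Analytic receptive field (pixels) at the bottleneck output.

    Composes layer receptive fields down the encoder path: each 3x3
    convolution at dilation d adds 2*d*jump, each stride-2 transition
    doubles the jump.
    """
    rf, jump = 1, 1
    dense = config.variant != "vanilla"
    enc_dil = config.max_dilation if config.variant in ("hd", "dd") else 1

    def block_growth(level_dil: int) -> int:
        n_convs = config.steps if dense else 2
        return sum(2 * level_dil * jump for _ in range(n_convs))

    if dense:
        rf += 2 * jump  # stem
    for _ in range(1, config.levels):
        rf += block_growth(enc_dil)
        rf += 2 * jump  # stride-2 down conv
        jump *= 2
    rf += block_growth(enc_dil)  # bottleneck block
    if config.variant == "hd":
        rf += 2 * 2 * jump  # residual bridge: two 3x3 convs
    return rf
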