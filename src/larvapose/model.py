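"""Keypoint-detection network with strip convolutions and a cross-tensor head.

The backbone is a bottleneck-style stem whose 3x3 stage is augmented by
chained pairs of 1xN / Nx1 "strip" convolutions (the combinatorial
convolution block), followed by HRNet-style multi-resolution stages with
all-to-all fusion.  Two variants are built from the published
high-resolution-network widths: B (32/64/128/256) and L (48/96/192/384).
The head emits either per-keypoint 2-D heatmaps or per-keypoint
width/height vector pairs (the cross-shaped heat tensor).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, ConvBNReLU, Identity, Module, Sequential

VARIANT_WIDTHS = {
    "B": (32, 64, 128, 256),   # high-resolution-network W32 widths
    "L": (48, 96, 192, 384),   # W48 widths
}


@dataclass
class CoConvBlockSpec:
    """Configuration of one combinatorial convolution block."""

    in_channels: int
    out_channels: int
    bottleneck_channels: int | None = None  # defaults to in_channels // 4
    branch_kernels: tuple[int, ...] = (5, 7, 9)
    include_3x3: bool = True
    inner_shortcut: bool = True

    def __post_init__(self) -> None:
        if self.bottleneck_channels is None:
            self.bottleneck_channels = max(self.in_channels // 4, 1)


class CoConvBlock(Module):
    """Bottleneck block whose middle 3x3 stage is a multi-scale strip-kernel sum.

    With the 1x1-reduced input r and branch kernels (5, 7, 9):

        h5 = f_1x5(r);  w5 = f_5x1(h5)
        h7 = f_1x7(r);  w7 = f_7x1(h7 + h5 + w5)
        h9 = f_1x9(r);  w9 = f_9x1(h9 + h5 + h7 + w5 + w7)
        core = f_3x3(r) + w5 + w7 + w9

    i.e. each vertical strip convolution receives, besides its own horizontal
    partner, the outputs of every smaller-scale branch (the inner shortcut).
    The core is 1x1-expanded, batch-normalized, added to the identity or
    projection shortcut and passed through ReLU, so the block is a drop-in
    replacement for a plain bottleneck.  With ``branch_kernels=()`` the block
    *is* a plain bottleneck.
    """

    def __init__(self, spec: CoConvBlockSpec, rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        mid = spec.bottleneck_channels
        self.reduce = ConvBNReLU(spec.in_channels, mid, 1, rng=rng)
        self.conv3 = Conv2d(mid, mid, (3, 3), rng=rng) if spec.include_3x3 else None
        self.branches_h = [Conv2d(mid, mid, (1, k), rng=rng) for k in spec.branch_kernels]
        self.branches_w = [Conv2d(mid, mid, (k, 1), rng=rng) for k in spec.branch_kernels]
        self.expand = Conv2d(mid, spec.out_channels, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(spec.out_channels)
        if spec.in_channels == spec.out_channels:
            self.shortcut = Identity()
        else:
            self.shortcut = Sequential(
                Conv2d(spec.in_channels, spec.out_channels, 1, bias=False, rng=rng),
                BatchNorm2d(spec.out_channels),
            )

    def forward(self, x: Tensor) -> Tensor:
        r = self.reduce(x)
        outputs = []          # w_k of each completed branch
        horizontals = []      # h_k of each completed branch
        for conv_h, conv_w in zip(self.branches_h, self.branches_w):
            h = conv_h(r)
            if self.spec.inner_shortcut and (horizontals or outputs):
                inner = ag.add_many([h] + horizontals + outputs)
            else:
                inner = h
            outputs.append(conv_w(inner))
            horizontals.append(h)
        core_terms = ([self.conv3(r)] if self.conv3 is not None else []) + outputs
        core = core_terms[0] if len(core_terms) == 1 else ag.add_many(core_terms)
        out = self.bn(self.expand(core))
        return ag.relu(ag.add(out, self.shortcut(x)))


def bottleneck_block(in_channels: int, out_channels: int,
                     bottleneck_channels: int | None = None,
                     rng: np.random.Generator | None = None) -> CoConvBlock:
    """A plain bottleneck: the strip-branch block with no strip branches."""
    return CoConvBlock(
        CoConvBlockSpec(in_channels, out_channels, bottleneck_channels,
                        branch_kernels=()),
        rng=rng,
    )


class BasicBlock(Module):
    """Two 3x3 conv-BN stages with a residual connection (per-branch unit)."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.conv1 = ConvBNReLU(channels, channels, 3, rng=rng)
        self.conv2 = ConvBNReLU(channels, channels, 3, rng=rng, relu=False)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(ag.add(self.conv2(self.conv1(x)), x))


class MultiResolutionStage(Module):
    """One integration/transition stage of the multi-branch backbone.

    Transition: carries existing branches over (channel-matching 3x3 conv if
    the width changes) and opens one new branch at half resolution via a
    stride-2 3x3 conv.  Integration: a basic residual block per branch, then
    all-to-all fusion (stride-2 3x3 conv chains downward, 1x1 conv plus
    nearest upsampling upward, summation, ReLU).
    """

    def __init__(self, in_widths: tuple[int, ...], out_widths: tuple[int, ...], rng=None):
        super().__init__()
        if len(out_widths) not in (len(in_widths), len(in_widths) + 1):
            raise ConfigurationError("a stage may add at most one branch")
        self.in_widths = in_widths
        self.out_widths = out_widths
        self.transitions = []
        for t, width in enumerate(out_widths):
            if t < len(in_widths):
                if in_widths[t] == width:
                    self.transitions.append(Identity())
                else:
                    self.transitions.append(ConvBNReLU(in_widths[t], width, 3, rng=rng))
            else:
                self.transitions.append(
                    ConvBNReLU(in_widths[-1], width, 3, stride=2, rng=rng))
        self.blocks = [BasicBlock(w, rng=rng) for w in out_widths]
        # fuse_paths[t][s]: module mapping branch s to branch t's resolution/width
        self.fuse_paths: list[list[Module]] = []
        n = len(out_widths)
        for t in range(n):
            row: list[Module] = []
            for s in range(n):
                if s == t:
                    row.append(Identity())
                elif s < t:  # downsample by stride-2 conv chain
                    steps = []
                    cin = out_widths[s]
                    for k in range(t - s):
                        cout = out_widths[t] if k == t - s - 1 else cin
                        steps.append(ConvBNReLU(cin, cout, 3, stride=2, rng=rng,
                                                relu=(k != t - s - 1)))
                        cin = cout
                    row.append(Sequential(*steps))
                else:  # upsample: 1x1 conv then nearest-neighbour x2^(s-t)
                    row.append(Sequential(
                        ConvBNReLU(out_widths[s], out_widths[t], 1, rng=rng, relu=False),
                        _Upsample(2 ** (s - t)),
                    ))
            self.fuse_paths.append(row)
        # flat alias so the base-class attribute scan discovers the fusion modules
        self._flat_fuse = [m for row in self.fuse_paths for m in row]

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        carried = [self.transitions[t](xs[min(t, len(xs) - 1)])
                   for t in range(len(self.out_widths))]
        carried = [blk(x) for blk, x in zip(self.blocks, carried)]
        fused = []
        for t in range(len(carried)):
            terms = [self.fuse_paths[t][s](carried[s]) for s in range(len(carried))]
            fused.append(ag.relu(ag.add_many(terms)))
        return fused


class _Upsample(Module):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest(x, self.factor)


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters of the full network."""

    variant: str = "B"                  # B, L, or custom
    in_channels: int = 3
    stem_channels: int = 64
    n_coconv_blocks: int = 4
    coconv_channels: int = 256
    widths: tuple[int, ...] | None = None   # derived from variant when None
    n_stages: int = 4
    head_channels: int = 26
    head_mode: str = "csht"             # "csht" or "heatmap"
    csht_filter_kernel: int = 3
    coconv_branch_kernels: tuple[int, ...] = (5, 7, 9)

    def __post_init__(self) -> None:
        if self.widths is None:
            if self.variant not in VARIANT_WIDTHS:
                raise ConfigurationError(
                    f"unknown variant {self.variant!r}; expected one of "
                    f"{sorted(VARIANT_WIDTHS)} or explicit widths")
            self.widths = VARIANT_WIDTHS[self.variant]
        if self.head_mode not in ("csht", "heatmap"):
            raise ConfigurationError(f"unknown head_mode {self.head_mode!r}")
        if self.n_stages < 1:
            raise ConfigurationError("n_stages must be >= 1")


class CshtHead(Module):
    """Cross-shaped-tensor head: axis pooling, channel mixer, per-axis filter.

    Per keypoint channel the width vector is the column-wise mean and the
    height vector the row-wise mean of the 26-channel feature map.  The two
    vectors are laid side by side (shape-unified to one long vector), mixed
    across channels by a 1x1 convolution, filtered by a short 1-D
    convolution per axis position, and split back.  The mixer initializes to
    the identity and the filter to a centred delta with zero bias, so an
    untrained head reproduces pure average pooling.
    """

    def __init__(self, channels: int, filter_kernel: int = 3, rng=None):
        super().__init__()
        self.channels = channels
        self.mixer = Conv2d(channels, channels, (1, 1), rng=rng)
        self.filter = Conv2d(channels, channels, (1, filter_kernel), rng=rng)
        self.set_identity()

    def set_identity(self) -> None:
        """Reset mixer/filter to the exact pooling-equivalent initialization."""
        c = self.channels
        self.mixer.weight.data[...] = np.eye(c)[:, :, None, None]
        self.mixer.bias.data[...] = 0.0
        self.filter.weight.data[...] = 0.0
        mid = self.filter.weight.data.shape[3] // 2
        self.filter.weight.data[np.arange(c), np.arange(c), 0, mid] = 1.0
        self.filter.bias.data[...] = 0.0

    def forward(self, features: Tensor) -> tuple[Tensor, Tensor]:
        N, C, H, W = features.shape
        wv = ag.mean_axis(features, 2)   # (N, C, W) column-wise mean
        hv = ag.mean_axis(features, 3)   # (N, C, H) row-wise mean
        joined = ag.concat([wv, hv], axis=2)
        joined = ag.reshape(joined, (N, C, 1, W + H))
        mixed = self.filter(self.mixer(joined))
        mixed = ag.reshape(mixed, (N, C, W + H))
        return ag.narrow(mixed, 2, 0, W), ag.narrow(mixed, 2, W, H)


class CSHTNet(Module):
    """Full forward graph: stem, strip-conv blocks, multi-branch stages, head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.output_stride = 4
        self.head_channels = spec.head_channels
        self.head_mode = spec.head_mode
        self.stem1 = ConvBNReLU(spec.in_channels, spec.stem_channels, 3, stride=2, rng=rng)
        self.stem2 = ConvBNReLU(spec.stem_channels, spec.stem_channels, 3, stride=2, rng=rng)
        blocks = []
        cin = spec.stem_channels
        for _ in range(spec.n_coconv_blocks):
            blocks.append(CoConvBlock(CoConvBlockSpec(
                cin, spec.coconv_channels,
                bottleneck_channels=max(spec.stem_channels // 4, 4),
                branch_kernels=spec.coconv_branch_kernels), rng=rng))
            cin = spec.coconv_channels
        self.coconv_blocks = blocks
        widths = spec.widths
        self.entry = [
            ConvBNReLU(spec.coconv_channels, widths[0], 3, rng=rng),
            ConvBNReLU(spec.coconv_channels, widths[1] if len(widths) > 1 else widths[0],
                       3, stride=2, rng=rng),
        ]
        stages = []
        current = tuple(widths[:2]) if len(widths) > 1 else (widths[0],)
        for _ in range(spec.n_stages):
            nxt = tuple(widths[:min(len(current) + 1, len(widths))])
            stages.append(MultiResolutionStage(current, nxt, rng=rng))
            current = nxt
        self.stages = stages
        self.final_conv = Conv2d(widths[0], spec.head_channels, 1, rng=rng)
        self.head = CshtHead(spec.head_channels, spec.csht_filter_kernel, rng=rng) \
            if spec.head_mode == "csht" else Identity()

    def forward(self, x: Tensor):
        """Maps (N, C, H, W) input to 26-channel output at stride 4.

        Returns an (N, K, H/4, W/4) tensor in heatmap mode, or a
        (width_vectors, height_vectors) pair of shapes (N, K, W/4) and
        (N, K, H/4) in cross-tensor mode.
        """
        y = self.stem2(self.stem1(x))
        for block in self.coconv_blocks:
            y = block(y)
        branches = [entry(y) for entry in self.entry[:max(1, min(2, len(self.spec.widths)))]]
        for stage in self.stages:
            branches = stage(branches)
        features = self.final_conv(branches[0])
        if self.spec.head_mode == "heatmap":
            return features
        return self.head(features)


def build_network(spec: NetworkSpec, seed: int = 0) -> CSHTNet:
    """Construct the network for a validated spec (B/L variants or custom widths)."""
    return CSHTNet(spec, seed=seed)


def tiny_network_spec(head_mode: str = "csht", n_keypoints: int = 26,
                      in_channels: int = 1) -> NetworkSpec:
    """A desk-scale configuration for CPU training experiments and smoke tests."""
    return NetworkSpec(
        variant="tiny",
        in_channels=in_channels,
        stem_channels=16,
        n_coconv_blocks=1,
        coconv_channels=32,
        widths=(16, 32),
        n_stages=1,
        head_channels=n_keypoints,
        head_mode=head_mode,
    )


def count_parameters(network: Module) -> int:
    """Exact number of parameter scalars in the network."""
    return nn.count_parameters(network)


def summary(network: CSHTNet, input_size: tuple[int, int] = (384, 288)) -> str:
    """Human-readable module list with parameter counts and the output shapes."""
    buf = io.StringIO()
    w, h = input_size
    print(f"input: ({network.spec.in_channels}, {h}, {w})  [C, H, W]", file=buf)
    for name, child in network.children():
        print(f"  {name}: {type(child).__name__} "
              f"({nn.count_parameters(child)} params)", file=buf)
    network.eval()
    out = network(Tensor(np.zeros((1, network.spec.in_channels, h, w), dtype=np.float32)))
    if isinstance(out, tuple):
        print(f"output: width vectors {out[0].shape}, height vectors {out[1].shape}",
              file=buf)
    else:
        print(f"output: heatmaps {out.shape}", file=buf)
    print(f"total parameters: {nn.count_parameters(network)}", file=buf)
    return buf.getvalue()
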