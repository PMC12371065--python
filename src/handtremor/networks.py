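"""Classifier branches: GhostNet and the Improved LinkNet.

GhostNet builds its feature maps cheaply: each ghost module produces a
fraction ``1/s`` of its output channels with a dense convolution and the rest
with depthwise ("cheap") transforms of those primary maps, cutting parameters
roughly by the ratio ``s``.  Ghost bottlenecks pair two modules with a
residual shortcut (identity at stride 1, a downsampling path at stride 2).

The Improved LinkNet is an encoder-decoder classifier with three encoder
blocks distinguished by activation (LeakyReLU / ELU / Swish) and pooling
(average / average+mixed / none), a multi-branch MDSCM block - three Gabor
filtered, multi-kernel (3/5/7) convolution branches XOR-fused with the
encoder outputs and concatenated - and decoders normalized by WAP-BN, a
batch-norm variant modulated by a weighted-average-pooled statistic
``S_J = (1 - gamma) * mean(window)``.  Note the degeneracy: at ``gamma = 1``
``S_J`` is identically zero and the WAP-BN output vanishes, so the shipped
default is ``gamma = 0.5``.

Both branches map a fused feature vector - reshaped and zero-padded into a
square single-channel map - to a two-class probability vector.  All weights
are He-initialized from a single config seed; forward passes in inference
mode are pure functions of (weights, input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "wap",
    "wap_bn",
    "mixed_pool",
    "xor_fuse",
    "gabor_kernel",
    "GhostModuleSpec",
    "GhostModule",
    "GhostBottleneck",
    "GhostNet",
    "GhostNetSpec",
    "MdscmSpec",
    "Mdscm",
    "ImprovedLinkNet",
    "LinkNetSpec",
    "vector_to_map",
    "ghost_module_param_count",
    "dense_conv_param_count",
]


# ---------------------------------------------------------------------------
# array-level operations (the oracle-checkable primitives)


def wap(window: np.ndarray, gamma: float) -> float:
    """Weighted average pooling: ``(1 - gamma) * mean(window)``."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    return float((1.0 - gamma) * window.mean())


def wap_bn(
    z: np.ndarray, gamma: float = 0.5, eps: float = 1e-5, s_j: float | None = None
) -> np.ndarray:
    """Weighted-average-pooling batch normalization of a flat window.

    ``(Z * S_J - mean(Z) * S_J) / sqrt(var(Z) + sigmoid(S_J) + eps)`` where
    ``S_J = wap(Z, gamma)`` unless supplied explicitly.
    """
    z = np.asarray(z, dtype=np.float64)
    if s_j is None:
        s_j = wap(z, gamma)
    mean = z.mean()
    var = z.var()
    return (z * s_j - mean * s_j) / np.sqrt(var + 1.0 / (1.0 + np.exp(-s_j)) + eps)


def mixed_pool(x: np.ndarray, lam: float) -> np.ndarray:
    """``lam * maxpool2 + (1 - lam) * avgpool2`` on an NCHW array."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    n, c, h, w = x.shape
    blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
    return lam * blocks.max(axis=(3, 5)) + (1 - lam) * blocks.mean(axis=(3, 5))


def xor_fuse(
    a: np.ndarray, b: np.ndarray, mode: str = "soft", threshold: float = 0.0
) -> np.ndarray:
    """XOR of two real-valued maps.

    ``soft`` (default, differentiable) is the elementwise absolute difference
    |a - b|; ``binary`` thresholds both maps at ``threshold``, XORs the bits
    and casts back to {0, 1} floats.  Identical inputs give all zeros in both
    modes.
    """
    if mode == "soft":
        return np.abs(a - b)
    if mode == "binary":
        return np.logical_xor(a > threshold, b > threshold).astype(np.float64)
    raise ValueError("mode must be 'soft' or 'binary'")


def gabor_kernel(
    theta: float,
    wavelength: float = 8.0,
    phase: float = 0.0,
    sigma: float = 4.0,
    aspect: float = 0.5,
    half_width: int = 3,
) -> np.ndarray:
    """Real Gabor kernel: oriented Gaussian envelope times a cosine carrier."""
    offs = np.arange(-half_width, half_width + 1, dtype=np.float64)
    y, x = np.meshgrid(offs, offs, indexing="ij")
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(xr**2 + aspect**2 * yr**2) / (2 * sigma**2))
    kernel = envelope * np.cos(2 * np.pi * xr / wavelength + phase)
    return kernel - kernel.mean()  # zero-DC so flat regions give no response


# ---------------------------------------------------------------------------
# ghost modules


@dataclass(frozen=True)
class GhostModuleSpec:
    in_channels: int
    out_channels: int
    ratio: int = 2  # primary:cheap split s
    primary_kernel: int = 1
    cheap_kernel: int = 3
    stride: int = 1
    relu: bool = True

    def __post_init__(self) -> None:
        if self.out_channels % self.ratio != 0:
            raise ValueError(
                f"out_channels={self.out_channels} not divisible by ratio={self.ratio}"
            )
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


def ghost_module_param_count(spec: GhostModuleSpec) -> int:
    """Convolution weights of a ghost module (primary + cheap, no BN/bias)."""
    primary = spec.out_channels // spec.ratio
    cheap = primary * (spec.ratio - 1)
    return (
        spec.in_channels * primary * spec.primary_kernel**2
        + cheap * spec.cheap_kernel**2
    )


def dense_conv_param_count(in_channels: int, out_channels: int, kernel: int) -> int:
    return in_channels * out_channels * kernel**2


class GhostModule(nn.Module):
    """Primary convolution for out/s channels; depthwise cheap maps for the rest."""

    def __init__(self, spec: GhostModuleSpec, rng: np.random.Generator):
        self.spec = spec
        primary = spec.out_channels // spec.ratio
        self.primary = nn.Conv2d(
            spec.in_channels,
            primary,
            spec.primary_kernel,
            stride=spec.stride,
            bias=False,
            rng=rng,
        )
        self.bn1 = nn.BatchNorm2d(primary)
        self.cheap = (
            nn.DepthwiseConv2d(
                primary, spec.ratio - 1, spec.cheap_kernel, bias=False, rng=rng
            )
            if spec.ratio > 1
            else None
        )
        self.bn2 = nn.BatchNorm2d(primary * (spec.ratio - 1)) if self.cheap else None

    def forward(self, x: Tensor) -> Tensor:
        p = self.bn1(self.primary(x))
        if self.spec.relu:
            p = nn.relu(p)
        if self.cheap is None:
            return p
        c = self.bn2(self.cheap(p))
        if self.spec.relu:
            c = nn.relu(c)
        return nn.concat([p, c], axis=1)


class GhostBottleneck(nn.Module):
    """Two ghost modules with a residual shortcut.

    Stride 1 keeps shapes (identity shortcut); stride 2 downsamples through a
    depthwise conv between the modules, with a depthwise + pointwise shortcut.
    The second ghost module has no activation before the residual addition.
    """

    def __init__(
        self,
        in_channels: int,
        expansion: int,
        out_channels: int,
        stride: int,
        rng: np.random.Generator,
        ratio: int = 2,
    ):
        self.stride = stride
        self.ghost1 = GhostModule(
            GhostModuleSpec(in_channels, expansion, ratio=ratio), rng
        )
        self.down = (
            nn.DepthwiseConv2d(expansion, 1, 3, stride=2, bias=False, rng=rng)
            if stride == 2
            else None
        )
        self.down_bn = nn.BatchNorm2d(expansion) if stride == 2 else None
        self.ghost2 = GhostModule(
            GhostModuleSpec(expansion, out_channels, ratio=ratio, relu=False), rng
        )
        if stride == 1 and in_channels == out_channels:
            self.shortcut = None
        else:
            self.short_dw = nn.DepthwiseConv2d(
                in_channels, 1, 3, stride=stride, bias=False, rng=rng
            )
            self.short_pw = nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
            self.short_bn = nn.BatchNorm2d(out_channels)
            self.shortcut = "projection"

    def forward(self, x: Tensor) -> Tensor:
        y = self.ghost1(x)
        if self.down is not None:
            y = self.down_bn(self.down(y))
        y = self.ghost2(y)
        if self.shortcut is None:
            return y + x
        s = self.short_bn(self.short_pw(self.short_dw(x)))
        return y + s


@dataclass(frozen=True)
class GhostNetSpec:
    in_channels: int = 1
    stem_channels: int = 16
    # (expansion, out_channels, stride) per bottleneck
    bottlenecks: tuple[tuple[int, int, int], ...] = (
        (16, 16, 1),
        (48, 24, 2),
        (72, 40, 2),
        (120, 80, 2),
    )
    n_classes: int = 2
    seed: int = 0


class GhostNet(nn.Module):
    """Stem convolution, ghost bottleneck stack, GAP, softmax head (Gn^o)."""

    def __init__(self, spec: GhostNetSpec | None = None):
        spec = spec or GhostNetSpec()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        self.stem = nn.Conv2d(
            spec.in_channels, spec.stem_channels, 3, stride=2, bias=False, rng=rng
        )
        self.stem_bn = nn.BatchNorm2d(spec.stem_channels)
        blocks = []
        in_ch = spec.stem_channels
        for expansion, out_ch, stride in spec.bottlenecks:
            blocks.append(GhostBottleneck(in_ch, expansion, out_ch, stride, rng))
            in_ch = out_ch
        self.blocks = blocks
        self.head = nn.Linear(in_ch, spec.n_classes, rng=rng)

    def logits(self, x: Tensor) -> Tensor:
        y = nn.relu(self.stem_bn(self.stem(x)))
        for block in self.blocks:
            y = block(y)
        return self.head(nn.global_avg_pool(y))

    def forward(self, x: Tensor) -> np.ndarray:
        """Per-class probabilities (N, n_classes)."""
        return nn.softmax(self.logits(x).data)


# ---------------------------------------------------------------------------
# MDSCM and Improved LinkNet


@dataclass(frozen=True)
class MdscmSpec:
    gabor_thetas: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2)
    gabor_wavelength: float = 8.0
    gabor_phase: float = 0.0
    gabor_sigma: float = 4.0
    gabor_aspect: float = 0.5
    conv_kernels: tuple[int, int, int] = (3, 5, 7)
    xor_mode: str = "soft"
    binarize_threshold: float = 0.0


class Mdscm(nn.Module):
    """Multi-branch module: Gabor -> conv(k_i) -> BN, XOR with encoder i, concat.

    Branch outputs are average-pooled to their matching encoder's spatial
    size; the XOR-fused maps are then aligned to the smallest size before
    channel concatenation.  Soft XOR (|a - b|) keeps the block differentiable.
    """

    def __init__(
        self,
        in_channels: int,
        branch_channels: tuple[int, int, int],
        spec: MdscmSpec,
        rng: np.random.Generator,
    ):
        self.spec = spec
        self.gabors = [
            Tensor(
                gabor_kernel(
                    theta,
                    spec.gabor_wavelength,
                    spec.gabor_phase,
                    spec.gabor_sigma,
                    spec.gabor_aspect,
                )[None, None]
                * np.ones((1, in_channels, 1, 1))
            )  # fixed (untrained) oriented filter bank
            for theta in spec.gabor_thetas
        ]
        self.convs = [
            nn.Conv2d(1, ch, k, bias=False, rng=rng)
            for ch, k in zip(branch_channels, spec.conv_kernels)
        ]
        self.bns = [nn.BatchNorm2d(ch) for ch in branch_channels]

    @staticmethod
    def _pool_to(x: Tensor, target: int) -> Tensor:
        while x.data.shape[-1] > target:
            x = nn.avg_pool2d(x)
        return x

    def forward(self, x: Tensor, encoder_outputs: list[Tensor]) -> Tensor:
        if len(encoder_outputs) != 3:
            raise ValueError("MDSCM needs exactly three encoder maps")
        fused = []
        min_side = min(e.data.shape[-1] for e in encoder_outputs)
        for gab, conv, bn, enc in zip(self.gabors, self.convs, self.bns, encoder_outputs):
            branch = nn.conv2d(x, gab, None, stride=1, pad=gab.data.shape[-1] // 2)
            branch = bn(conv(branch))
            if branch.data.shape[-1] < enc.data.shape[-1]:
                raise ValueError(
                    f"cannot align branch {branch.data.shape} to encoder {enc.data.shape}"
                )
            branch = self._pool_to(branch, enc.data.shape[-1])
            if self.spec.xor_mode == "soft":
                f = (branch - enc).abs()
            else:
                f = Tensor(
                    xor_fuse(
                        branch.data, enc.data, "binary", self.spec.binarize_threshold
                    )
                )
            fused.append(self._pool_to(f, min_side))
        return nn.concat(fused, axis=1)


@dataclass(frozen=True)
class LinkNetSpec:
    in_channels: int = 1
    encoder_channels: tuple[int, int, int] = (8, 16, 32)
    mdscm: MdscmSpec = field(default_factory=MdscmSpec)
    wap_gamma: float = 0.5
    mixed_lambda: float = 0.5
    n_classes: int = 2
    seed: int = 0


class ImprovedLinkNet(nn.Module):
    """Three-encoder LinkNet variant with MDSCM fusion and WAP-BN decoders.

    Encoder 1: conv-BN-LeakyReLU-avgpool; encoder 2: conv-BN-ELU followed by
    a parallel average/mixed pooling combination; encoder 3: conv-BN-Swish
    (no pooling).  MDSCM fuses the input with the three encoder outputs; the
    decoders upsample back with additive skip connections from the matching
    encoders, each followed by WAP-BN; global average pooling and a linear
    head give the class scores (ILn^o).
    """

    MIN_SIDE = 8

    def __init__(self, spec: LinkNetSpec | None = None):
        spec = spec or LinkNetSpec()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        c1, c2, c3 = spec.encoder_channels
        self.enc1 = nn.Conv2d(spec.in_channels, c1, 3, bias=False, rng=rng)
        self.enc1_bn = nn.BatchNorm2d(c1)
        self.enc2 = nn.Conv2d(c1, c2, 3, bias=False, rng=rng)
        self.enc2_bn = nn.BatchNorm2d(c2)
        self.enc3 = nn.Conv2d(c2, c3, 3, bias=False, rng=rng)
        self.enc3_bn = nn.BatchNorm2d(c3)
        self.mdscm = Mdscm(spec.in_channels, (c1, c2, c3), spec.mdscm, rng)
        self.dec3 = nn.Conv2d(c1 + c2 + c3, c2, 3, bias=False, rng=rng)
        self.dec3_norm = nn.WapBN2d(c2, gamma=spec.wap_gamma)
        self.dec2 = nn.Conv2d(c2, c1, 3, bias=False, rng=rng)
        self.dec2_norm = nn.WapBN2d(c1, gamma=spec.wap_gamma)
        self.dec1 = nn.Conv2d(c1, c1, 3, bias=False, rng=rng)
        self.dec1_norm = nn.WapBN2d(c1, gamma=spec.wap_gamma)
        self.head = nn.Linear(c1, spec.n_classes, rng=rng)

    def _check_input(self, x: Tensor) -> None:
        side = x.data.shape[-1]
        if side % 4 != 0 or side < self.MIN_SIDE:
            raise ValueError(
                f"input side {side} must be a multiple of 4 and >= {self.MIN_SIDE} "
                "(two 2x2 pooling stages)"
            )

    def logits(self, x: Tensor) -> Tensor:
        self._check_input(x)
        lam = self.spec.mixed_lambda
        # encoders
        e1 = nn.avg_pool2d(nn.leaky_relu(self.enc1_bn(self.enc1(x))))  # S/2
        y = nn.elu(self.enc2_bn(self.enc2(e1)))
        avg = nn.avg_pool2d(y)
        mixed = nn.max_pool2d(y) * lam + avg * (1.0 - lam)
        e2 = (avg + mixed) * 0.5  # parallel average + mixed pooling, stride 2
        e3 = nn.swish(self.enc3_bn(self.enc3(e2)))  # S/4
        # multi-scale fusion
        m = self.mdscm(x, [e1, e2, e3])  # at S/4
        # decoders with additive skips, WAP-BN after each conv
        d3 = nn.relu(self.dec3_norm(self.dec3(m)) + e2)
        d2 = nn.relu(self.dec2_norm(self.dec2(nn.upsample_nearest2(d3))) + e1)
        d1 = nn.relu(self.dec1_norm(self.dec1(nn.upsample_nearest2(d2))))
        return self.head(nn.global_avg_pool(d1))

    def forward(self, x: Tensor) -> np.ndarray:
        """Per-class probabilities (N, n_classes)."""
        return nn.softmax(self.logits(x).data)


# ---------------------------------------------------------------------------
# feature-vector input


def vector_to_map(vector: np.ndarray, multiple: int = 4) -> np.ndarray:
    """Reshape a feature vector to a zero-padded square single-channel map.

    The side is ``ceil(sqrt(len))`` rounded up to a multiple of the pooling
    chain's requirement (4 by default).
    """
    v = np.asarray(vector, dtype=np.float64).ravel()
    side = int(np.ceil(np.sqrt(v.size)))
    side = max(int(np.ceil(side / multiple)) * multiple, ImprovedLinkNet.MIN_SIDE)
    padded = np.zeros(side * side)
    padded[: v.size] = v
    return padded.reshape(side, side)
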