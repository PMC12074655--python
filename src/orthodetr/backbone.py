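"""Orthogonal channel-shuffle backbone.

Each block is a residual unit whose channel attention comes not from global
average pooling but from projecting every channel of the post-conv feature
map F (b, c, h, w) onto a fixed special-orthogonal filter of side n = h = w:

    f[b, i] = sum_{h,w} F[b, i] * W_i          (per-channel projection)
    alpha   = sigmoid(FC2(relu(FC1(f))))       (channel weights in (0, 1))
    out     = relu(channel_shuffle(alpha * F + shortcut(X), groups))

The filters are frozen draws from SO(n) (or a between-filter Gram-Schmidt
bank for the ablation); only the convs, norms and the attention MLP train.
A single ReLU follows the shuffle — applying one both before and after a
pure channel permutation is mathematically redundant, since a permutation
commutes with any elementwise map.

Because the filters require square feature maps, the backbone raises on
non-square inputs unless ``pad_to_square`` is set, which symmetrically
zero-pads before each attention step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ortho_filters import FilterBank, build_filter_bank

__all__ = [
    "OrthoShuffleBlockConfig",
    "BackboneConfig",
    "orthogonal_projection",
    "channel_shuffle",
    "AttentionMLP",
    "OrthoShuffleBlock",
    "Backbone",
    "build_backbone",
]


def orthogonal_projection(F, bank: FilterBank):
    """Project each channel of F (b, c, h, w) onto its filter: elementwise
    product with W_i then a spatial sum, giving coefficients (b, c).

    Accepts a Tensor (stays on the autodiff graph; the filters are constants)
    or a plain array (returns an array).
    """
    shape = F.shape
    b, c, h, w = shape
    if h != w:
        raise ValueError(f"attention path needs a square map, got {h}x{w}")
    if h != bank.n:
        raise ValueError(f"feature side {h} does not match filter side {bank.n}")
    if c != bank.c:
        raise ValueError(f"channel count {c} does not match bank channels {bank.c}")
    if isinstance(F, Tensor):
        W = Tensor(bank.stack[np.newaxis])         # (1, c, n, n), frozen
        return (F * W).sum(axis=(2, 3))
    return np.einsum("bchw,chw->bc", np.asarray(F, dtype=np.float64), bank.stack)


def channel_shuffle(F, groups: int):
    """Interleave channel groups: reshape (g, c/g) -> transpose -> flatten.

    Pure permutation of channels; spatial content is untouched. Works on
    Tensors and arrays alike.
    """
    b, c, h, w = F.shape
    if c % groups != 0:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    return (F.reshape(b, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(b, c, h, w))


def shuffle_permutation(c: int, groups: int) -> np.ndarray:
    """The channel permutation :func:`channel_shuffle` applies."""
    return np.arange(c).reshape(groups, c // groups).T.reshape(-1)


@dataclass(frozen=True)
class OrthoShuffleBlockConfig:
    in_channels: int
    out_channels: int
    stride: int = 1
    shuffle_groups: int = 2
    attention_reduction: int = 16
    seed: int = 0
    use_norm: bool = True

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.out_channels % self.shuffle_groups != 0:
            raise ValueError("out_channels must be divisible by shuffle_groups")

    @property
    def attention_hidden(self) -> int:
        return max(1, self.out_channels // self.attention_reduction)


class AttentionMLP(ad.Module):
    """FC -> ReLU -> FC -> sigmoid producing per-channel weights in (0, 1)."""

    def __init__(self, rng: np.random.Generator, c: int, hidden: int):
        self.fc1 = ad.Linear(rng, c, hidden)
        self.fc2 = ad.Linear(rng, hidden, c)

    def __call__(self, f: Tensor) -> Tensor:
        return self.fc2(self.fc1(f).relu()).sigmoid()


class _ConvNorm(ad.Module):
    def __init__(self, rng, cin, cout, k, stride, use_norm):
        self.w = ad.param(rng, cout, cin, k, k)
        self.b = ad.zeros_param(cout)
        self.use_norm = use_norm
        if use_norm:
            self.gamma = ad.ones_param(cout)
            self.beta = ad.zeros_param(cout)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)
        if self.use_norm:
            y = ad.batch_norm(y, self.gamma, self.beta)
        return y


class OrthoShuffleBlock(ad.Module):
    """One orthogonal channel-shuffle residual block.

    Filter banks are supplied per forward spatial side by the owning
    backbone (or created on demand for standalone use).
    """

    def __init__(self, cfg: OrthoShuffleBlockConfig, rng: np.random.Generator,
                 ortho_mode: str = "special_orthogonal"):
        self.cfg = cfg
        self.ortho_mode = ortho_mode
        self.conv1 = _ConvNorm(rng, cfg.in_channels, cfg.out_channels, 3, cfg.stride, cfg.use_norm)
        self.conv2 = _ConvNorm(rng, cfg.out_channels, cfg.out_channels, 3, 1, cfg.use_norm)
        self.attn = AttentionMLP(rng, cfg.out_channels, cfg.attention_hidden)
        self.needs_shortcut_proj = cfg.stride != 1 or cfg.in_channels != cfg.out_channels
        if self.needs_shortcut_proj:
            self.shortcut = _ConvNorm(rng, cfg.in_channels, cfg.out_channels, 1, cfg.stride, cfg.use_norm)
        self._banks: dict[int, FilterBank] = {}

    def bank_for(self, side: int) -> FilterBank:
        if side not in self._banks:
            self._banks[side] = build_filter_bank(
                self.cfg.out_channels, side, self.ortho_mode, self.cfg.seed + side)
        return self._banks[side]

    def __call__(self, x: Tensor, alpha_override: Tensor | None = None) -> Tensor:
        F = self.conv2(self.conv1(x).relu())
        side = F.shape[2]
        if F.shape[2] != F.shape[3]:
            raise ValueError(f"attention path needs a square map, got {F.shape[2]}x{F.shape[3]}")
        if alpha_override is None:
            f = orthogonal_projection(F, self.bank_for(side))
            alpha = self.attn(f)
        else:
            alpha = alpha_override
        b, c = alpha.shape
        F_attn = F * alpha.reshape(b, c, 1, 1)
        F_res = self.shortcut(x) if self.needs_shortcut_proj else x
        merged = F_attn + F_res
        return channel_shuffle(merged, self.cfg.shuffle_groups).relu()


@dataclass(frozen=True)
class BackboneConfig:
    input_side: int = 640
    in_channels: int = 1
    stem_channels: int = 16
    stage_channels: tuple[int, ...] = (64, 128, 256)
    stage_depths: tuple[int, ...] = (2, 2, 2)
    shuffle_groups: int = 2
    attention_reduction: int = 16
    ortho_mode: str = "special_orthogonal"
    use_norm: bool = True
    pad_to_square: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_side % 32 != 0:
            raise ValueError(f"input side must be divisible by 32, got {self.input_side}")
        if len(self.stage_channels) != 3 or len(self.stage_depths) != 3:
            raise ValueError("exactly three stages (S3/S4/S5) are expected")


class Backbone(ad.Module):
    """Stem (stride 4) + three shuffle-block stages emitting S3/S4/S5 at
    strides 8/16/32."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem1 = _ConvNorm(rng, cfg.in_channels, cfg.stem_channels, 3, 2, cfg.use_norm)
        self.stem2 = _ConvNorm(rng, cfg.stem_channels, cfg.stem_channels, 3, 2, cfg.use_norm)
        self.stages: list[list[OrthoShuffleBlock]] = []
        cin = cfg.stem_channels
        for si, (cout, depth) in enumerate(zip(cfg.stage_channels, cfg.stage_depths)):
            blocks = []
            for bi in range(depth):
                bcfg = OrthoShuffleBlockConfig(
                    in_channels=cin, out_channels=cout,
                    stride=2 if bi == 0 else 1,
                    shuffle_groups=cfg.shuffle_groups,
                    attention_reduction=cfg.attention_reduction,
                    seed=cfg.seed + 1000 * (si + 1) + 10 * bi,
                    use_norm=cfg.use_norm)
                blocks.append(OrthoShuffleBlock(bcfg, rng, cfg.ortho_mode))
                cin = cout
            self.stages.append(blocks)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if x.shape[2] != x.shape[3]:
            if not self.cfg.pad_to_square:
                raise ValueError("non-square input; set pad_to_square to enable padding")
            x = _pad_square(x)
        y = self.stem2(self.stem1(x).relu()).relu()
        outs = []
        for blocks in self.stages:
            for blk in blocks:
                y = blk(y)
            outs.append(y)
        return tuple(outs)  # S3, S4, S5


def _pad_square(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    side = max(h, w)
    dh, dw = side - h, side - w
    top, left = dh // 2, dw // 2
    data = np.zeros((b, c, side, side))
    out = Tensor(data, _prev=(x,))
    out.data[:, :, top:top + h, left:left + w] = x.data

    def _bw():
        x._accumulate(out.grad[:, :, top:top + h, left:left + w])

    out._backward = _bw
    return out


def build_backbone(cfg: BackboneConfig) -> Backbone:
    """Construct the backbone; outputs are deterministic in (cfg.seed, input)."""
    return Backbone(cfg)
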