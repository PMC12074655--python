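"""Hybrid encoder: intra-scale attention on the deepest map, convolutional
cross-scale fusion below it.

Only S5 — the deepest, most semantic scale — receives attention (AIFI):
flatten, deformable attention, FFN, with residuals and layer norm, reshape
back. The three scales are then fused by a PAN-style pathway (CCFM):
top-down with nearest-neighbour x2 upsampling, bottom-up with stride-2
convs; each fusion concatenates two adjacent scales, reduces channels 1x1
and applies a run of RepBlocks. Where the two pathways meet at a scale the
maps are combined by element-wise addition. Channel width is a single
hidden dim at every scale.

RepBlocks train as 3x3 conv + 1x1 conv + identity (summed, then ReLU) and
deploy as one algebraically merged 3x3 conv — the merged kernel is
W3 + pad(W1) + I, so the two modes agree exactly up to float round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .deform_attention import DATConfig, DeformableAttention

__all__ = [
    "EncoderConfig",
    "RepBlock",
    "FusionBlock",
    "AIFI",
    "HybridEncoder",
]


class RepBlock(ad.Module):
    """Re-parameterisable conv block (in_channels must equal out_channels
    for the identity branch)."""

    def __init__(self, rng: np.random.Generator, c: int):
        self.c = c
        self.w3 = ad.param(rng, c, c, 3, 3)
        self.b3 = ad.zeros_param(c)
        self.w1 = ad.param(rng, c, c, 1, 1)
        self.b1 = ad.zeros_param(c)

    def __call__(self, x: Tensor, mode: str = "train", activate: bool = True) -> Tensor:
        if x.shape[1] != self.c:
            raise ValueError(f"identity branch needs {self.c} channels, got {x.shape[1]}")
        if mode == "train":
            y = ad.conv2d(x, self.w3, self.b3, stride=1, pad=1) \
                + ad.conv2d(x, self.w1, self.b1, stride=1, pad=0) + x
        elif mode == "deploy":
            wm, bm = self.reparameterize()
            y = ad.conv2d(x, Tensor(wm), Tensor(bm), stride=1, pad=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return y.relu() if activate else y

    def reparameterize(self) -> tuple[np.ndarray, np.ndarray]:
        """Merge the three branches into a single 3x3 kernel + bias."""
        c = self.c
        wm = self.w3.data.copy()
        wm[:, :, 1, 1] += self.w1.data[:, :, 0, 0]       # 1x1 sits at the centre tap
        wm[np.arange(c), np.arange(c), 1, 1] += 1.0      # identity branch
        bm = self.b3.data + self.b1.data
        return wm, bm


class FusionBlock(ad.Module):
    """Concatenate two same-resolution maps, reduce 1x1, run RepBlocks."""

    def __init__(self, rng: np.random.Generator, c: int, n_rep: int = 3):
        self.reduce_w = ad.param(rng, c, 2 * c, 1, 1)
        self.reduce_b = ad.zeros_param(c)
        self.reps = [RepBlock(rng, c) for _ in range(n_rep)]

    def __call__(self, a: Tensor, b: Tensor, mode: str = "train") -> Tensor:
        x = ad.concat([a, b], axis=1)
        x = ad.conv2d(x, self.reduce_w, self.reduce_b, stride=1, pad=0)
        for rep in self.reps:
            x = rep(x, mode=mode)
        return x


class FFN(ad.Module):
    def __init__(self, rng: np.random.Generator, d: int, expansion: int = 4):
        self.fc1 = ad.Linear(rng, d, d * expansion)
        self.fc2 = ad.Linear(rng, d * expansion, d)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class AIFI(ad.Module):
    """Attention-based intra-scale interaction on the S5 plane only."""

    def __init__(self, dat_cfg: DATConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        d = dat_cfg.dim
        self.dat = DeformableAttention(dat_cfg)
        self.ffn = FFN(rng, d)
        self.ln1_g, self.ln1_b = ad.ones_param(d), ad.zeros_param(d)
        self.ln2_g, self.ln2_b = ad.ones_param(d), ad.zeros_param(d)

    def __call__(self, s5: Tensor) -> Tensor:
        b, c, h, w = s5.shape
        if h != w:
            raise ValueError("AIFI expects a square S5 map")
        att = self.dat(s5)
        t = (s5 + att).reshape(b, c, h * w).transpose(0, 2, 1)       # tokens
        t = ad.layer_norm(t, self.ln1_g, self.ln1_b)
        t = ad.layer_norm(t + self.ffn(t), self.ln2_g, self.ln2_b)
        return t.transpose(0, 2, 1).reshape(b, c, h, w)


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: tuple[int, int, int] = (64, 128, 256)
    hidden_dim: int = 256
    heads: int = 8
    r: int = 1
    s: float = 2.0
    bias_enabled: bool = True
    bias_table_side: int = 31
    n_rep: int = 3
    use_norm: bool = True
    seed: int = 0


class HybridEncoder(ad.Module):
    """Project S3/S4/S5 to the hidden dim, AIFI on S5, CCFM across scales."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim
        self.proj_w = [ad.param(rng, h, c, 1, 1) for c in cfg.in_channels]
        self.proj_b = [ad.zeros_param(h) for _ in cfg.in_channels]
        if cfg.use_norm:
            self.proj_g = [ad.ones_param(h) for _ in cfg.in_channels]
            self.proj_beta = [ad.zeros_param(h) for _ in cfg.in_channels]
        self.aifi = AIFI(DATConfig(dim=h, heads=cfg.heads, r=cfg.r, s=cfg.s,
                                   bias_enabled=cfg.bias_enabled,
                                   bias_table_side=cfg.bias_table_side,
                                   seed=cfg.seed + 7),
                         seed=cfg.seed + 11)
        self.fuse_td4 = FusionBlock(rng, h, cfg.n_rep)
        self.fuse_td3 = FusionBlock(rng, h, cfg.n_rep)
        self.fuse_bu4 = FusionBlock(rng, h, cfg.n_rep)
        self.fuse_bu5 = FusionBlock(rng, h, cfg.n_rep)
        self.down3 = _Down(rng, h)
        self.down4 = _Down(rng, h)

    def _project(self, maps: tuple[Tensor, Tensor, Tensor]) -> list[Tensor]:
        out = []
        for i, m in enumerate(maps):
            y = ad.conv2d(m, self.proj_w[i], self.proj_b[i], stride=1, pad=0)
            if self.cfg.use_norm:
                y = ad.batch_norm(y, self.proj_g[i], self.proj_beta[i])
            out.append(y)
        return out

    def ccfm(self, s3: Tensor, s4: Tensor, s5: Tensor, mode: str = "train") -> tuple[Tensor, Tensor, Tensor]:
        """Cross-scale fusion of already-projected maps."""
        p5 = s5
        p4 = self.fuse_td4(ad.upsample2x(p5), s4, mode)
        p3 = self.fuse_td3(ad.upsample2x(p4), s3, mode)
        n3 = p3
        n4 = self.fuse_bu4(self.down3(n3), p4, mode) + p4
        n5 = self.fuse_bu5(self.down4(n4), p5, mode) + p5
        return n3, n4, n5

    def __call__(self, s3: Tensor, s4: Tensor, s5: Tensor, mode: str = "train") -> tuple[Tensor, Tensor, Tensor]:
        p3, p4, p5 = self._project((s3, s4, s5))
        p5 = self.aifi(p5)
        return self.ccfm(p3, p4, p5, mode)


class _Down(ad.Module):
    """Stride-2 3x3 conv halving spatial size."""

    def __init__(self, rng: np.random.Generator, c: int):
        self.w = ad.param(rng, c, c, 3, 3)
        self.b = ad.zeros_param(c)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=2, pad=1)
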