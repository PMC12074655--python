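"""Deformable attention over a 2-D feature map.

Instead of attending to every position, a uniform reference grid of
H_G x W_G points (the map downsampled by ``r``) is shifted by learned,
bounded offsets Delta_p = s * tanh(theta_offset(q)); keys and values are
bilinearly sampled at the shifted points, and scaled-dot-product attention
runs between the full set of queries and only those H_G * W_G sampled
keys — linear spatial complexity in the key set. An interpolated relative-
position bias table (Swin-style, but indexed by *continuous* normalised
displacements) can be added to the attention logits.

Coordinate convention throughout: normalised (x, y) in [-1, +1], with
(-1, -1) the top-left and (+1, +1) the bottom-right pixel centre. An axis
with a single point normalises to 0 (its centre). Out-of-range sampling
coordinates are clamped to the border.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "DATConfig",
    "ReferenceGrid",
    "make_reference_grid",
    "compute_offsets",
    "bilinear_sample",
    "relative_position_bias",
    "DeformableAttention",
    "reference_attention",
]


@dataclass(frozen=True)
class ReferenceGrid:
    """Uniform grid of normalised reference points, shape (H_G, W_G, 2)."""

    points: np.ndarray
    r: int

    @property
    def h(self) -> int:
        return self.points.shape[0]

    @property
    def w(self) -> int:
        return self.points.shape[1]

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1, 2)


def _axis_coords(n: int) -> np.ndarray:
    # u -> 2u/(n-1) - 1; a single-point axis sits at the centre, 0
    if n == 1:
        return np.zeros(1)
    u = np.arange(n, dtype=np.float64)
    return 2.0 * u / (n - 1) - 1.0


def make_reference_grid(H: int, W: int, r: int) -> ReferenceGrid:
    """Reference points for an H x W map downsampled by r (r | H, r | W)."""
    if H % r != 0 or W % r != 0:
        raise ValueError(f"downsample factor {r} must divide H={H} and W={W}")
    hg, wg = H // r, W // r
    xs = _axis_coords(wg)
    ys = _axis_coords(hg)
    pts = np.stack(np.meshgrid(xs, ys, indexing="xy"), axis=-1)  # (hg, wg, 2) as (x, y)
    return ReferenceGrid(pts, r)


class OffsetNet(ad.Module):
    """theta_offset: pools the query map and linearly predicts one (dx, dy)
    per grid cell. Depth-1 by design; the contract is only that offsets are
    a differentiable function of the queries, bounded by ``s`` via tanh."""

    def __init__(self, rng: np.random.Generator, dim: int, n_points: int):
        self.proj = ad.Linear(rng, dim, n_points * 2)
        self.n_points = n_points

    def __call__(self, q: Tensor) -> Tensor:
        pooled = q.mean(axis=1)                       # (b, dim)
        return self.proj(pooled).reshape(q.shape[0], self.n_points, 2)


def compute_offsets(q: Tensor, offset_net: OffsetNet, s: float) -> Tensor:
    """Delta_p = s * tanh(theta_offset(q)); every entry bounded by s."""
    if s <= 0:
        raise ValueError("offset amplitude s must be positive")
    return offset_net(q).tanh() * s


def bilinear_sample(x, coords):
    """4-neighbour bilinear interpolation of a (b, c, h, w) map at
    normalised (x, y) coordinates (b, n, 2) (or (n, 2), broadcast over the
    batch). Accepts Tensors (differentiable) or arrays."""
    arr_in = not isinstance(x, Tensor) and not isinstance(coords, Tensor)
    xt = x if isinstance(x, Tensor) else Tensor(x)
    ct = coords if isinstance(coords, Tensor) else Tensor(np.asarray(coords, dtype=np.float64))
    if ct.ndim == 2:
        b = xt.shape[0]
        n = ct.shape[0]
        # broadcast the same coordinate set across the batch (graph-safe)
        ct = ct.reshape(1, n, 2) + Tensor(np.zeros((b, n, 2)))
    out = ad.grid_sample(xt, ct)
    return out.data if arr_in else out


def relative_position_bias(table, p_q: np.ndarray, p_k) :
    """Interpolated bias B[i, j] for query positions p_q (n_q, 2) and key
    positions p_k (n_k, 2), both normalised to [-1, 1].

    The relative displacement (p_k - p_q)/2 (back in [-1, 1]) indexes the
    (side x side) parameter table by bilinear interpolation.
    """
    tt = table if isinstance(table, Tensor) else Tensor(np.asarray(table, dtype=np.float64))
    side = tt.shape[-1]
    pq = np.asarray(p_q, dtype=np.float64)
    pk_t = p_k if isinstance(p_k, Tensor) else Tensor(np.asarray(p_k, dtype=np.float64))
    n_q, n_k = pq.shape[0], pk_t.shape[0]
    disp = (pk_t.reshape(1, n_k, 2) + Tensor(-pq).reshape(n_q, 1, 2)) * 0.5  # (n_q, n_k, 2)
    grid = tt.reshape(1, 1, side, side)
    flat = disp.reshape(1, n_q * n_k, 2)
    out = ad.grid_sample(grid, flat).reshape(n_q, n_k)
    return out if (isinstance(table, Tensor) or isinstance(p_k, Tensor)) else out.data


@dataclass(frozen=True)
class DATConfig:
    dim: int
    heads: int = 8
    r: int = 1
    s: float = 2.0
    bias_enabled: bool = True
    bias_table_side: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim % self.heads != 0:
            raise ValueError(f"dim {self.dim} must be divisible by heads {self.heads}")


class DeformableAttention(ad.Module):
    """Deformable attention layer on a square-or-rectangular feature map.

    Forward: q = flatten(x) W_q; keys/values sampled at grid + offsets and
    projected with W_k / W_v; per-head softmax(q k^T / sqrt(d) + B) v, heads
    concatenated and output-projected back to map shape.
    """

    def __init__(self, cfg: DATConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.dim
        self.wq = ad.Linear(rng, d, d)
        self.wk = ad.Linear(rng, d, d)
        self.wv = ad.Linear(rng, d, d)
        self.wo = ad.Linear(rng, d, d)
        self.offset_net: OffsetNet | None = None   # built lazily per grid size
        self._offset_rng = np.random.default_rng(cfg.seed + 1)
        if cfg.bias_enabled:
            s = cfg.bias_table_side
            self.bias_table = Tensor(
                np.random.default_rng(cfg.seed + 2).normal(0.0, 0.02, (cfg.heads, s, s)),
                requires_grad=True)

    def _ensure_offset_net(self, n_points: int) -> OffsetNet:
        if self.offset_net is None or self.offset_net.n_points != n_points:
            self.offset_net = OffsetNet(self._offset_rng, self.cfg.dim, n_points)
        return self.offset_net

    def __call__(self, x: Tensor, return_attn: bool = False):
        cfg = self.cfg
        b, c, H, W = x.shape
        if c != cfg.dim:
            raise ValueError(f"channel dim {c} != configured dim {cfg.dim}")
        grid = make_reference_grid(H, W, cfg.r)
        n_k = grid.h * grid.w
        tokens = x.reshape(b, c, H * W).transpose(0, 2, 1)     # (b, N, c)
        q = self.wq(tokens)                                    # (b, N, c)

        net = self._ensure_offset_net(n_k)
        dp = compute_offsets(q, net, cfg.s)                    # (b, n_k, 2)
        ref = Tensor(np.broadcast_to(grid.flat()[None], (b, n_k, 2)).copy())
        coords = ref + dp
        sampled = ad.grid_sample(x, coords)                    # (b, n_k, c)
        k = self.wk(sampled)
        v = self.wv(sampled)

        heads, dh = cfg.heads, c // cfg.heads
        N = H * W

        def split(t: Tensor, n: int) -> Tensor:
            return t.reshape(b, n, heads, dh).transpose(0, 2, 1, 3)  # (b, h, n, dh)

        qh, kh, vh = split(q, N), split(k, n_k), split(v, n_k)
        logits = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))

        if cfg.bias_enabled:
            qpos = make_reference_grid(H, W, 1).flat()          # (N, 2)
            # displacement (key - query)/2 for every (image, query, key)
            disp = (coords.reshape(b, 1, n_k, 2)
                    + Tensor(-qpos.reshape(1, N, 1, 2))) * 0.5
            table = self.bias_table.reshape(1, heads, *self.bias_table.shape[1:])
            bias = ad.grid_sample(table, disp.reshape(1, b * N * n_k, 2))
            bias = bias.reshape(b, N, n_k, heads).transpose(0, 3, 1, 2)
            logits = logits + bias

        attn = ad.softmax(logits, axis=-1)                      # rows sum to 1
        z = attn @ vh                                           # (b, h, N, dh)
        z = z.transpose(0, 2, 1, 3).reshape(b, N, c)
        out = self.wo(z).transpose(0, 2, 1).reshape(b, c, H, W)
        if return_attn:
            return out, attn
        return out

    def zero_offsets_(self) -> None:
        """Force Delta_p = 0 (for limit checks): zero the offset projection."""
        if self.offset_net is not None:
            self.offset_net.proj.w.data[:] = 0.0
            self.offset_net.proj.b.data[:] = 0.0


def reference_attention(x: np.ndarray, wq, wk, wv, wo, heads: int) -> np.ndarray:
    """Independent plain multi-head attention (numpy only, no sampling):
    the limit deformable attention must match at zero offsets, no bias,
    r = 1. Weights are (w, b) pairs as plain arrays."""
    b, c, H, W = x.shape
    N = H * W
    t = x.reshape(b, c, N).transpose(0, 2, 1)
    lin = lambda a, wb: a @ wb[0] + wb[1]
    q, k, v = lin(t, wq), lin(t, wk), lin(t, wv)
    dh = c // heads
    out = np.empty_like(t)
    for bi in range(b):
        zs = []
        for m in range(heads):
            sl = slice(m * dh, (m + 1) * dh)
            logit = q[bi][:, sl] @ k[bi][:, sl].T / math.sqrt(dh)
            e = np.exp(logit - logit.max(axis=-1, keepdims=True))
            a = e / e.sum(axis=-1, keepdims=True)
            zs.append(a @ v[bi][:, sl])
        out[bi] = np.concatenate(zs, axis=-1)
    out = lin(out, wo)
    return out.transpose(0, 2, 1).reshape(b, c, H, W)
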