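"""Special-orthogonal filter sampling and validation.

The channel-attention mechanism at the heart of the backbone projects each
feature channel onto a fixed n x n filter. Two flavours of orthogonality are
supported:

* ``special_orthogonal`` — each filter is an independent Haar-distributed
  element of SO(n): orthonormal rows/columns *within* the filter, no
  constraint between filters. This is the within-filter scheme whose
  regularising effect (unit spectral norm, hence a non-expanding linear map)
  the package exists to exercise.
* ``gram_schmidt`` — filters are random matrices flattened to length-n^2
  vectors and orthonormalised *against each other* (the between-filter
  scheme of orthogonal-channel-attention precedent); requires c <= n^2.

Filters are frozen: they are sampled once from a seed and never receive
gradient updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OrthoMatrix",
    "FilterBank",
    "sample_special_orthogonal",
    "build_filter_bank",
    "verify_lipschitz_chain",
    "save_filter_bank",
    "load_filter_bank",
]

ORTHO_TOL = 1e-5


@dataclass(frozen=True)
class OrthoMatrix:
    """An n x n special-orthogonal matrix (R^T R = I, det R = +1)."""

    n: int
    entries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        R = np.asarray(self.entries, dtype=np.float64)
        if R.shape != (self.n, self.n):
            raise ValueError(f"entries must be {self.n}x{self.n}, got {R.shape}")
        object.__setattr__(self, "entries", R)
        dev = self.orthogonality_defect()
        if dev > ORTHO_TOL:
            raise ValueError(f"not orthogonal: max|R^T R - I| = {dev:.3g}")
        d = float(np.linalg.det(R))
        if abs(d - 1.0) > ORTHO_TOL:
            raise ValueError(f"determinant {d:.6f} != +1")

    def orthogonality_defect(self) -> float:
        R = self.entries
        return float(np.abs(R.T @ R - np.eye(self.n)).max())

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.entries))


@dataclass(frozen=True)
class FilterBank:
    """c filters of side n stacked along the channel axis.

    ``mode='special_orthogonal'``: each filter independently in SO(n).
    ``mode='gram_schmidt'``: flattened filters pairwise orthonormal.
    """

    c: int
    n: int
    stack: np.ndarray = field(repr=False)     # (c, n, n)
    mode: str = "special_orthogonal"
    seed: int = 0

    def matrices(self) -> list[OrthoMatrix]:
        if self.mode != "special_orthogonal":
            raise ValueError("per-filter SO(n) membership only holds in special_orthogonal mode")
        return [OrthoMatrix(self.n, self.stack[i], self.seed + i) for i in range(self.c)]

    def gram(self) -> np.ndarray:
        """Gram matrix of the flattened filters, shape (c, c)."""
        flat = self.stack.reshape(self.c, -1)
        return flat @ flat.T


def sample_special_orthogonal(n: int, seed: int) -> OrthoMatrix:
    """Draw a Haar-distributed element of SO(n).

    Construction: QR-decompose an i.i.d. standard-normal matrix, multiply Q
    by the signs of R's diagonal (this makes the draw Haar-uniform on O(n)),
    then negate one column if det = -1 to land on the rotation component.
    Deterministic for fixed (n, seed).
    """
    if n <= 0:
        raise ValueError(f"matrix side must be positive, got {n}")
    if n == 1:
        return OrthoMatrix(1, np.ones((1, 1)), seed)
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs[np.newaxis, :]
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return OrthoMatrix(n, Q, seed)


def build_filter_bank(c: int, n: int, mode: str = "special_orthogonal",
                      seed: int = 0) -> FilterBank:
    """Build c frozen filters of side n.

    Per-channel seeds are derived as ``seed + i`` so each filter is an
    independent, reproducible draw.
    """
    if c < 1:
        raise ValueError(f"channel count must be positive, got {c}")
    if n < 1:
        raise ValueError(f"filter side must be positive, got {n}")
    if mode == "special_orthogonal":
        stack = np.stack([sample_special_orthogonal(n, seed + i).entries for i in range(c)])
        return FilterBank(c, n, stack, mode, seed)
    if mode == "gram_schmidt":
        if c > n * n:
            raise ValueError(
                f"cannot orthonormalise {c} filters of dimension {n * n}: "
                "at most n^2 flattened filters can be mutually orthogonal"
            )
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal((c, n * n))
        # orthonormalise the c flattened filters against each other (QR on
        # the transposed stack gives the same span with orthonormal columns)
        Q, _ = np.linalg.qr(raw.T)            # (n^2, c), orthonormal columns
        stack = Q.T.reshape(c, n, n)
        return FilterBank(c, n, stack.copy(), mode, seed)
    raise ValueError(f"unknown mode {mode!r}")


def verify_lipschitz_chain(weight_mats: list[np.ndarray], x: np.ndarray,
                           y: np.ndarray) -> float:
    """Contraction ratio ||f(x) - f(y)|| / ||x - y|| through a ReLU chain.

    f = W_L . relu . ... . relu . W_1 with ReLU between layers (1-Lipschitz),
    so if every W_l has unit spectral norm the ratio cannot exceed 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    denom = float(np.linalg.norm(x - y))
    if denom == 0.0:
        raise ValueError("x and y coincide; contraction ratio undefined")

    def f(v: np.ndarray) -> np.ndarray:
        for i, W in enumerate(weight_mats):
            v = np.asarray(W) @ v
            if i < len(weight_mats) - 1:
                v = np.maximum(v, 0.0)
        return v

    return float(np.linalg.norm(f(x) - f(y))) / denom


# -- serialisation -----------------------------------------------------------

def save_filter_bank(bank: FilterBank, path: str | Path) -> None:
    """Write the raw float64 stack to ``path`` with a JSON sidecar
    ``path + '.json'`` recording (c, n, mode, seed) for bit-exact reload."""
    path = Path(path)
    bank.stack.astype(np.float64).tofile(path)
    meta = {"c": bank.c, "n": bank.n, "mode": bank.mode, "seed": bank.seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_filter_bank(path: str | Path) -> FilterBank:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stack = np.fromfile(path, dtype=np.float64).reshape(meta["c"], meta["n"], meta["n"])
    return FilterBank(meta["c"], meta["n"], stack, meta["mode"], meta["seed"])
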