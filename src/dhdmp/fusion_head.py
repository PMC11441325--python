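"""Fusion of the three pair representations and the conv-pool classifier.

For one (drug, microbe) pair the pipeline upstream produces three blocks:
the multi-node association representation (2 rows), the homogeneous/
heterogeneous neighbor block (4 rows), and the long-distance spatial block
(2 rows).  Their native widths differ, so each block passes through a
learned bias-free linear map to a common width ``d_fuse`` before vertical
stacking into an 8 x d_fuse feature map.  An ablated block is replaced by a
zero block of matching shape, preserving the map geometry.

The fused map goes through two convolution-pooling stages — kernels 2 x 10
then 1 x 10, max-pooling window 1 x 10 (stride = window) — is flattened,
and a fully connected layer with softmax yields the two-class probability
``p``; ``p[1]`` is the association score.  Training minimizes binary
cross-entropy on ``p[1]``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from .autograd import Parameter, Tensor, concat, conv2d

__all__ = [
    "fuse_representations",
    "conv_pool_forward",
    "predict_pair",
    "batch_loss",
    "FusionHeadModule",
]


def fuse_representations(Xmna, Bhhn, Flds, fusion_params: dict) -> np.ndarray:
    """Map each present block to width d_fuse and stack to 8 x d_fuse.

    ``fusion_params`` holds bias-free map matrices under keys
    ``'W_mna'`` (w1 x d_fuse), ``'W_hhn'``, ``'W_lds'``.  A block passed as
    ``None`` (ablation) contributes a zero block of matching shape.
    """
    if Xmna is None and Bhhn is None and Flds is None:
        raise ValueError("all three representation blocks are disabled")
    d_fuse = next(
        fusion_params[k].shape[1]
        for k, blk in (("W_mna", Xmna), ("W_hhn", Bhhn), ("W_lds", Flds))
        if blk is not None
    )
    rows = []
    for key, blk, nrows in (("W_mna", Xmna, 2), ("W_hhn", Bhhn, 4), ("W_lds", Flds, 2)):
        if blk is None:
            rows.append(np.zeros((nrows, d_fuse)))
        else:
            rows.append(np.asarray(blk, dtype=np.float64) @ fusion_params[key])
    return np.vstack(rows)


def _relu(x):
    return np.maximum(x, 0.0)


def conv_pool_forward(Zfin: np.ndarray, params: dict, pool: int = 10) -> np.ndarray:
    """Two (conv -> ReLU -> max-pool) stages on one fused map, flattened.

    ``params['conv']`` is a list of ``(W, b)`` with W of shape
    (Cout, Cin, kh, kw); convolutions are valid, stride 1; pooling is over
    non-overlapping width-``pool`` windows (trailing remainder dropped).
    """
    x = np.asarray(Zfin, dtype=np.float64)[None, None]  # (1, 1, H, W)
    for W, b in params["conv"]:
        cout, cin, kh, kw = W.shape
        B, c, hh, ww = x.shape
        if c != cin:
            raise ValueError(f"channel mismatch: input {c}, kernel expects {cin}")
        hout, wout = hh - kh + 1, ww - kw + 1
        if hout < 1 or wout < 1:
            raise ValueError(
                f"input {hh}x{ww} too small for kernel {kh}x{kw}"
            )
        out = np.zeros((B, cout, hout, wout))
        for i in range(kh):
            for j in range(kw):
                out += np.einsum(
                    "bchw,oc->bohw", x[:, :, i:i + hout, j:j + wout], W[:, :, i, j]
                )
        x = _relu(out + b[None, :, None, None])
        wkeep = (x.shape[3] // pool) * pool
        if wkeep < pool:
            raise ValueError(
                f"feature width {x.shape[3]} smaller than pooling window {pool}"
            )
        x = x[:, :, :, :wkeep].reshape(B, x.shape[1], x.shape[2], -1, pool).max(axis=-1)
    return x.reshape(-1)


def predict_pair(Zfin_final: np.ndarray, Wagg: np.ndarray, bagg: np.ndarray) -> np.ndarray:
    """Two-class softmax over the classifier logits; p[1] is the score."""
    logits = np.asarray(Zfin_final, dtype=np.float64) @ Wagg + bagg
    if not np.isfinite(logits).all():
        raise ValueError("non-finite classifier logits")
    e = np.exp(logits - logits.max())
    return e / e.sum()


def batch_loss(p_batch: np.ndarray, y_batch: np.ndarray,
               reduction: str = "mean") -> float:
    """Binary cross-entropy on the association probability p[1]."""
    p = np.asarray(p_batch, dtype=np.float64)
    y = np.asarray(y_batch, dtype=np.float64)
    p1 = p[:, 1] if p.ndim == 2 else p
    if p1.min() < 0 or p1.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    # xlogy handles the perfect-prediction endpoints (0 * log 0 = 0)
    per = -(xlogy(y, p1) + xlogy(1 - y, 1 - p1))
    if reduction == "mean":
        return float(per.mean())
    if reduction == "sum":
        return float(per.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def _glorot(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class FusionHeadModule:
    """Trainable fusion maps, conv-pool stack and classifier (batched)."""

    def __init__(self, widths: dict[str, int | None], d_fuse: int = 400,
                 conv_channels: tuple[int, int] = (16, 32), pool: int = 10,
                 rng: np.random.Generator | None = None):
        """``widths`` maps block name ('mna', 'hhn', 'lds') to native width,
        or None if that block is ablated."""
        rng = rng or np.random.default_rng(0)
        if all(w is None for w in widths.values()):
            raise ValueError("all three representation blocks are disabled")
        self.d_fuse = d_fuse
        self.pool = pool
        self.block_rows = {"mna": 2, "hhn": 4, "lds": 2}
        self.maps: dict[str, Parameter | None] = {}
        for name in ("mna", "hhn", "lds"):
            w = widths[name]
            self.maps[name] = None if w is None else Parameter(_glorot(rng, w, d_fuse))
        c1, c2 = conv_channels
        self.conv = [
            (Parameter(_glorot(rng, 1 * 2 * 10, c1, shape=(c1, 1, 2, 10))),
             Parameter(np.zeros(c1))),
            (Parameter(_glorot(rng, c1 * 1 * 10, c2, shape=(c2, c1, 1, 10))),
             Parameter(np.zeros(c2))),
        ]
        # trace shapes through the conv-pool stack to size the classifier
        h, w = 8, d_fuse
        for (W, _) in self.conv:
            kh, kw = W.shape[2], W.shape[3]
            h, w = h - kh + 1, w - kw + 1
            w = w // pool
            if w < 1:
                raise ValueError(
                    f"d_fuse={d_fuse} too small for kernels and pooling"
                )
        self.flat_width = c2 * h * w
        self.Wagg = Parameter(_glorot(rng, self.flat_width, 2))
        self.bagg = Parameter(np.zeros(2))

    def parameters(self) -> list[Parameter]:
        ps = [m for m in self.maps.values() if m is not None]
        for W, b in self.conv:
            ps += [W, b]
        return ps + [self.Wagg, self.bagg]

    def _maxpool_w(self, x: Tensor) -> Tensor:
        B, c, h, w = x.shape
        wkeep = (w // self.pool) * self.pool
        x = x[:, :, :, :wkeep]
        return x.reshape(B, c, h, wkeep // self.pool, self.pool).max(axis=-1)

    def forward(self, blocks: dict[str, Tensor | None]) -> Tensor:
        """Fuse a batch of pair blocks and return (B, 2) logits.

        ``blocks`` maps name to a (B, rows, native_width) tensor or None.
        """
        B = next(t.shape[0] for t in blocks.values() if t is not None)
        dtype = next(m.data.dtype for m in self.maps.values() if m is not None)
        parts = []
        for name in ("mna", "hhn", "lds"):
            t = blocks.get(name)
            if t is None or self.maps[name] is None:
                parts.append(Tensor(
                    np.zeros((B, self.block_rows[name], self.d_fuse), dtype=dtype)))
            else:
                parts.append(t @ self.maps[name])
        x = concat(parts, axis=1)                      # (B, 8, d_fuse)
        x = x.reshape(B, 1, 8, self.d_fuse)
        for W, b in self.conv:
            x = self._maxpool_w(conv2d(x, W, b).relu())
        flat = x.reshape(B, self.flat_width)
        return flat @ self.Wagg + self.bagg

    @staticmethod
    def loss(logits: Tensor, y: np.ndarray, reduction: str = "mean") -> Tensor:
        """Cross-entropy on the two-class logits (p[1] = association)."""
        lp = logits.log_softmax(axis=-1)
        y = np.asarray(y, dtype=np.float64)
        per = -(lp[:, 1] * y + lp[:, 0] * (1.0 - y))
        return per.mean() if reduction == "mean" else per.sum()
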