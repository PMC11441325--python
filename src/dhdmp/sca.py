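"""Patch-based spatial self/cross attention (SCA) over pairwise attributes.

A drug's and a microbe's raw attribute vectors (rows of Z, length Nd+Nm)
are zero-padded to a multiple of the patch size P and reshaped row-major
into N x P patch matrices.  Per attention head, shared weight matrices
WQ/WK/WV (P x Ndim) produce queries, keys and values for both streams of a
pair; scaled dot-product attention (divisor sqrt(Ndim)) is computed within
each stream (self) and across streams (cross), the two perspectives are
summed elementwise, heads are concatenated, and the two streams are
flattened and stacked into the 2 x (N * heads * Ndim) long-distance
representation of the pair.

Sharing WQ/WK/WV between the drug and microbe streams of a pair lets one
head score drug and microbe patches in a common space; heads are distinct.
Padding happens before projection, so pad zeros take part in attention like
real entries.  No positional encoding and no dropout are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "PatchMatrix",
    "patchify",
    "head_attention",
    "combine_perspectives",
    "multihead_concat",
    "pair_lds",
    "ScaModule",
]


@dataclass
class PatchMatrix:
    """Row-major N x P reshape of a zero-padded attribute vector."""

    patches: np.ndarray
    pad_len: int

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]

    def flatten_truncate(self) -> np.ndarray:
        """Undo patchify exactly: flatten row-major and drop the pad."""
        flat = self.patches.reshape(-1)
        return flat[: flat.size - self.pad_len] if self.pad_len else flat


def patchify(z: np.ndarray, P: int) -> PatchMatrix:
    """Zero-pad ``z`` to the next multiple of ``P`` and reshape to N x P."""
    if P < 1:
        raise ValueError(f"patch size must be >= 1, got {P}")
    z = np.asarray(z, dtype=np.float64).reshape(-1)
    pad_len = (-len(z)) % P
    padded = np.concatenate([z, np.zeros(pad_len)]) if pad_len else z
    return PatchMatrix(patches=padded.reshape(-1, P), pad_len=pad_len)


def _softmax_rows(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def head_attention(Zd_pat: np.ndarray, Zm_pat: np.ndarray,
                   WQ: np.ndarray, WK: np.ndarray, WV: np.ndarray):
    """Self- and cross-attention outputs of one head for both streams.

    Returns ``(F_self_drg, F_cross_drg, F_self_mic, F_cross_mic)``, each
    N x Ndim.  Cross-attention reads the other stream's values: the drug's
    queries attend over microbe keys and aggregate microbe values, and
    symmetrically for the microbe stream.
    """
    if Zd_pat.shape != Zm_pat.shape:
        raise ValueError(
            f"patch-count mismatch: {Zd_pat.shape} vs {Zm_pat.shape}"
        )
    ndim = WQ.shape[1]
    scale = 1.0 / np.sqrt(ndim)
    Qd, Kd, Vd = Zd_pat @ WQ, Zd_pat @ WK, Zd_pat @ WV
    Qm, Km, Vm = Zm_pat @ WQ, Zm_pat @ WK, Zm_pat @ WV
    f_self_d = _softmax_rows(Qd @ Kd.T * scale) @ Vd
    f_cross_d = _softmax_rows(Qd @ Km.T * scale) @ Vm
    f_self_m = _softmax_rows(Qm @ Km.T * scale) @ Vm
    f_cross_m = _softmax_rows(Qm @ Kd.T * scale) @ Vd
    return f_self_d, f_cross_d, f_self_m, f_cross_m


def combine_perspectives(F_self: np.ndarray, F_cross: np.ndarray) -> np.ndarray:
    """Elementwise sum of the self- and cross-attention outputs."""
    if F_self.shape != F_cross.shape:
        raise ValueError(f"shape mismatch: {F_self.shape} vs {F_cross.shape}")
    return F_self + F_cross


def multihead_concat(per_head_F: list[np.ndarray]) -> np.ndarray:
    """Concatenate head outputs along the feature axis: N x (M * Ndim)."""
    if not per_head_F:
        raise ValueError("at least one attention head is required")
    return np.concatenate(per_head_F, axis=-1)


def pair_lds(F_drg: np.ndarray, F_mic: np.ndarray) -> np.ndarray:
    """Flatten each stream row-major and stack: drug row first."""
    if F_drg.shape != F_mic.shape:
        raise ValueError(f"shape mismatch: {F_drg.shape} vs {F_mic.shape}")
    return np.vstack([F_drg.reshape(-1), F_mic.reshape(-1)])


class ScaModule:
    """Trainable multi-head SCA over batches of pairs.

    The patch matrices of all nodes are precomputed from Z (they are
    constants of a forward pass); per batch, drug and microbe patch stacks
    are gathered and attended head by head.
    """

    def __init__(self, patch_size: int = 50, ndim: int = 50, heads: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.patch_size = patch_size
        self.ndim = ndim
        self.heads = heads
        limit = np.sqrt(6.0 / (patch_size + ndim))
        self.weights = [
            tuple(Parameter(rng.uniform(-limit, limit, size=(patch_size, ndim)))
                  for _ in range(3))
            for _ in range(heads)
        ]

    def parameters(self) -> list[Parameter]:
        return [w for head in self.weights for w in head]

    def node_patches(self, Z: np.ndarray) -> np.ndarray:
        """Patchify every node's attribute row: (Nd+Nm, N, P) array."""
        return np.stack([patchify(row, self.patch_size).patches for row in Z])

    def out_width(self, attr_width: int) -> int:
        n_patches = -(-attr_width // self.patch_size)
        return n_patches * self.heads * self.ndim

    def forward(self, drug_patches: Tensor, microbe_patches: Tensor) -> Tensor:
        """Batched SCA.

        Inputs are (B, N, P) patch stacks for the drug and microbe of each
        pair; output is the (B, 2, N*heads*Ndim) long-distance block.
        """
        scale = float(1.0 / np.sqrt(self.ndim))
        heads_d, heads_m = [], []
        for WQ, WK, WV in self.weights:
            Qd, Kd, Vd = drug_patches @ WQ, drug_patches @ WK, drug_patches @ WV
            Qm, Km, Vm = microbe_patches @ WQ, microbe_patches @ WK, microbe_patches @ WV
            KdT = Kd.transpose(0, 2, 1)
            KmT = Km.transpose(0, 2, 1)
            f_d = ((Qd @ KdT) * scale).softmax(-1) @ Vd \
                + ((Qd @ KmT) * scale).softmax(-1) @ Vm
            f_m = ((Qm @ KmT) * scale).softmax(-1) @ Vm \
                + ((Qm @ KdT) * scale).softmax(-1) @ Vd
            heads_d.append(f_d)
            heads_m.append(f_m)
        F_d = concat(heads_d, axis=-1)   # (B, N, M*Ndim)
        F_m = concat(heads_m, axis=-1)
        B = F_d.shape[0]
        flat_d = F_d.reshape(B, 1, -1)
        flat_m = F_m.reshape(B, 1, -1)
        return concat([flat_d, flat_m], axis=1)
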