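"""Graph convolution with cross-graph feature propagation (GCNFP).

Two stacks of linear graph-convolution layers run side by side over the
joint node set:

* the *homogeneous* stack propagates attributes over the block-diagonal
  similarity adjacency:  ``B_homo^l = Ahomo @ B_homo^{l-1} @ W_homo^l``;
* the *heterogeneous* stack propagates over the bipartite association
  adjacency, and at every layer receives the same-order homogeneous
  features, scaled per node by a trainable coefficient vector alpha_g
  (the node feature propagation strategy, NFPS):

      B_hete^l = Ahete @ [ B_hete^{l-1} || diag(alpha_g) @ B_homo^l ] @ W_hete^l

Both stacks start from the attribute matrix Z (order 0).  Per node, the
orders 0..Lgcn are concatenated and projected to a low-dimensional space
with a Tanh layer; drugs and microbes use separate projection weights, and
the homogeneous/heterogeneous streams likewise have their own.  For a
(drug, microbe) pair the four projected vectors are stacked into a
4 x d_proj block.

No activation sits between propagation layers (the propagation is linear;
nonlinearity enters at the Tanh projection).
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "homo_forward",
    "hete_forward",
    "concat_orders",
    "project_low_dim",
    "pair_hhn",
    "GcnfpModule",
]


def homo_forward(Z: np.ndarray, Ahomo: np.ndarray,
                 weights: list[np.ndarray]) -> list[np.ndarray]:
    """Homogeneous propagation; returns all orders 0..Lgcn (order 0 = Z)."""
    if len(weights) < 1:
        raise ValueError("at least one propagation layer is required")
    layers = [np.asarray(Z, dtype=np.float64)]
    for W in weights:
        prev = layers[-1]
        if prev.shape[1] != W.shape[0]:
            raise ValueError(
                f"width mismatch: features {prev.shape[1]} vs weight {W.shape[0]}"
            )
        layers.append(Ahomo @ prev @ W)
    return layers


def hete_forward(Z: np.ndarray, Ahete: np.ndarray, homo_layers: list[np.ndarray],
                 weights: list[np.ndarray], alpha_g: np.ndarray) -> list[np.ndarray]:
    """Heterogeneous propagation with per-node-scaled homogeneous injection."""
    layers = [np.asarray(Z, dtype=np.float64)]
    alpha = np.asarray(alpha_g, dtype=np.float64).reshape(-1)
    for l, W in enumerate(weights, start=1):
        prev = layers[-1]
        aux = alpha[:, None] * homo_layers[l]
        cat = np.concatenate([prev, aux], axis=1)
        if cat.shape[1] != W.shape[0]:
            raise ValueError(
                f"layer {l}: concatenated width {cat.shape[1]} != weight input "
                f"width {W.shape[0]}"
            )
        layers.append(Ahete @ cat @ W)
    return layers


def concat_orders(layers: list[np.ndarray], node_index: int) -> np.ndarray:
    """One node's rows across orders 0..Lgcn, joined into a single vector."""
    if not layers:
        raise ValueError("empty layer list")
    return np.concatenate([layer[node_index] for layer in layers])


def project_low_dim(vec: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tanh projection into the low-dimensional feature space."""
    vec = np.asarray(vec, dtype=np.float64)
    if W.shape[1] != vec.shape[-1]:
        raise ValueError(f"width mismatch: weight {W.shape} vs vector {vec.shape}")
    return np.tanh(vec @ W.T + b)


def pair_hhn(i: int, j: int, projections: dict[str, np.ndarray],
             n_drugs: int) -> np.ndarray:
    """Stack the four projected vectors of a (drug, microbe) pair.

    Row order: drug-homogeneous, drug-heterogeneous, microbe-homogeneous,
    microbe-heterogeneous.  ``projections`` maps stream name ('homo'/'hete')
    to the full (Nd+Nm) x d_proj projected matrix.
    """
    return np.vstack([
        projections["homo"][i],
        projections["hete"][i],
        projections["homo"][n_drugs + j],
        projections["hete"][n_drugs + j],
    ])


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GcnfpModule:
    """Trainable homogeneous/heterogeneous stacks plus Tanh projections.

    alpha_g initializes to ones, so early training matches the unscaled
    concatenation; it is trained jointly with everything else.  Setting
    ``use_nfps=False`` freezes alpha_g at zero, which reduces the
    heterogeneous stack to plain propagation with a zero-padded block.
    """

    def __init__(self, n_drugs: int, n_microbes: int, attr_width: int,
                 lgcn: int = 2, hidden: int = 256, d_proj: int = 128,
                 use_nfps: bool = True, alpha_init: float = 1.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        n = n_drugs + n_microbes
        self.n_drugs = n_drugs
        self.lgcn = lgcn
        self.d_proj = d_proj
        self.use_nfps = use_nfps
        widths = [attr_width] + [hidden] * lgcn
        self.W_homo = [Parameter(_glorot(rng, widths[l], widths[l + 1]))
                       for l in range(lgcn)]
        self.W_hete = [Parameter(_glorot(rng, widths[l] + widths[l + 1], widths[l + 1]))
                       for l in range(lgcn)]
        self.alpha_g = Parameter(np.full(n, alpha_init if use_nfps else 0.0))
        total = sum(widths)
        # separate drug/microbe projections for each stream
        self.proj = {}
        for stream in ("homo", "hete"):
            for kind in ("drug", "microbe"):
                self.proj[(stream, kind)] = (
                    Parameter(_glorot(rng, total, d_proj)),
                    Parameter(np.zeros(d_proj)),
                )

    def parameters(self) -> list[Parameter]:
        ps = list(self.W_homo) + list(self.W_hete)
        if self.use_nfps:
            ps.append(self.alpha_g)
        for W, b in self.proj.values():
            ps += [W, b]
        return ps

    def forward(self, Z: Tensor, Ahomo: Tensor, Ahete: Tensor) -> dict[str, Tensor]:
        """Return the full projected matrices for both streams.

        Output: {'homo': (n, d_proj) Tensor, 'hete': (n, d_proj) Tensor},
        where drug rows went through the drug projection and microbe rows
        through the microbe projection.
        """
        homo = [Z]
        for W in self.W_homo:
            homo.append(Ahomo @ homo[-1] @ W)
        hete = [Z]
        alpha = self.alpha_g if self.use_nfps else Tensor(self.alpha_g.data)
        for l, W in enumerate(self.W_hete, start=1):
            aux = homo[l] * alpha.reshape(-1, 1)
            hete.append(Ahete @ concat([hete[-1], aux], axis=1) @ W)
        nd = self.n_drugs
        out = {}
        for stream, layers in (("homo", homo), ("hete", hete)):
            multi = concat(layers, axis=1)
            Wd, bd = self.proj[(stream, "drug")]
            Wm, bm = self.proj[(stream, "microbe")]
            drugs = (multi[:nd] @ Wd + bd).tanh()
            microbes = (multi[nd:] @ Wm + bm).tanh()
            out[stream] = concat([drugs, microbes], axis=0)
        return out
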