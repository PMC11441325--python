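"""Node category-sensitive hypergraph convolution (NHCN).

A hypergraph over all drug and microbe nodes is built *dynamically*: a
trainable hyperedge embedding matrix ``E`` ((Nd+Nm) x Ne) is multiplied with
the node attribute matrix ``Z`` to give the incidence-like matrix
``H = clamp(Z @ E, 0)``, whose entry (i, j) measures how strongly node i
belongs to hyperedge j.  Because ``E`` is trained, the hypergraph topology
changes as learning proceeds.

Drugs and microbes have heterogeneous feature distributions, so each node
also carries a *category feature* vector: all drugs share one trainable
initial vector, all microbes another.  Convolution propagates the
category-augmented attributes ``X = [Z || Y]`` through the hypergraph:

    X^{l} = LeakyReLU( DB^{-1/2} H DE^{-1} H^T DB^{-1/2} X^{l-1} )

with DB/DE the node/hyperedge degree matrices (row/column sums of H).
Zero degrees are treated as pseudo-inverses (0), so empty hyperedges and
isolated nodes are inert.

The functions here are plain-numpy reference implementations used for
construction, inspection and testing; the trainable path lives in
:class:`NhcnModule`, which expresses the same formulas on autograd tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "CategoryFeatures",
    "HypergraphState",
    "init_category_features",
    "build_dynamic_hypergraph",
    "nhcn_layer",
    "nhcn_forward",
    "pair_mna",
    "NhcnModule",
]


@dataclass
class CategoryFeatures:
    """Trainable per-node category features; one shared row per node type."""

    Y: np.ndarray  # (Nd+Nm, dim)
    dim: int


@dataclass
class HypergraphState:
    """Incidence-like matrix and degree vectors of the current hypergraph."""

    H: np.ndarray        # (Nd+Nm, Ne), non-negative
    node_degree: np.ndarray   # row sums of H (diagonal of DB)
    edge_degree: np.ndarray   # column sums of H (diagonal of DE)
    Ne: int


def init_category_features(n_drugs: int, n_microbes: int, dim: int,
                           seed: int, scale: float = 0.1) -> CategoryFeatures:
    """Draw one random category vector per node type and tile it.

    All drug rows are identical, all microbe rows are identical, and the two
    type vectors differ (they are independent continuous draws).
    """
    if dim < 1:
        raise ValueError(f"category feature width must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    y_drug = rng.normal(scale=scale, size=dim)
    y_microbe = rng.normal(scale=scale, size=dim)
    Y = np.vstack([np.tile(y_drug, (n_drugs, 1)), np.tile(y_microbe, (n_microbes, 1))])
    return CategoryFeatures(Y=Y, dim=dim)


def build_dynamic_hypergraph(Z: np.ndarray, E: np.ndarray) -> HypergraphState:
    """Incidence matrix ``H = max(Z @ E, 0)`` and its degree vectors.

    ``E`` is signed after random initialization while degrees must be
    non-negative, hence the elementwise clamp at zero.
    """
    Z = np.asarray(Z, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    if Z.shape[1] != E.shape[0]:
        raise ValueError(
            f"attribute width {Z.shape[1]} != hyperedge embedding height {E.shape[0]}"
        )
    H = np.maximum(Z @ E, 0.0)
    return HypergraphState(
        H=H,
        node_degree=H.sum(axis=1),
        edge_degree=H.sum(axis=0),
        Ne=E.shape[1],
    )


def _safe_pow(x: np.ndarray, p: float) -> np.ndarray:
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** p
    return out


def nhcn_layer(Xprev: np.ndarray, state: HypergraphState,
               leaky_slope: float = 0.01) -> np.ndarray:
    """One hypergraph convolution: normalized two-step propagation + LeakyReLU."""
    Xprev = np.asarray(Xprev, dtype=np.float64)
    if not np.isfinite(Xprev).all():
        raise ValueError("non-finite entries in the input feature map")
    db_inv_sqrt = _safe_pow(state.node_degree, -0.5)
    de_inv = _safe_pow(state.edge_degree, -1.0)
    Hn = db_inv_sqrt[:, None] * state.H          # DB^{-1/2} H
    prop = Hn * de_inv[None, :] @ (Hn.T @ Xprev)  # ... DE^{-1} H^T DB^{-1/2} X
    return np.where(prop > 0, prop, leaky_slope * prop)


def nhcn_forward(Z: np.ndarray, Y: np.ndarray, E: np.ndarray, Lhnn: int = 2,
                 leaky_slope: float = 0.01) -> np.ndarray:
    """Run ``Lhnn`` convolution layers on the category-augmented attributes.

    The hypergraph is rebuilt from the current (Z, E) once per forward pass
    and shared by all layers; E itself evolves only through training.
    """
    if Lhnn < 1:
        raise ValueError(f"layer count must be >= 1, got {Lhnn}")
    state = build_dynamic_hypergraph(Z, E)
    X = np.concatenate([Z, Y], axis=1)
    for _ in range(Lhnn):
        X = nhcn_layer(X, state, leaky_slope=leaky_slope)
    return X


def pair_mna(Xtilde: np.ndarray, i: int, j: int, n_drugs: int) -> np.ndarray:
    """Multi-node association representation of pair (drug i, microbe j):
    the drug's and the microbe's rows of the final feature map, stacked."""
    n = Xtilde.shape[0]
    n_microbes = n - n_drugs
    if not 0 <= i < n_drugs:
        raise IndexError(f"drug index {i} out of range [0, {n_drugs})")
    if not 0 <= j < n_microbes:
        raise IndexError(f"microbe index {j} out of range [0, {n_microbes})")
    return np.vstack([Xtilde[i], Xtilde[n_drugs + j]])


class NhcnModule:
    """Trainable NHCN: hyperedge embedding + category features.

    Parameters are initialized from a seeded generator; the forward pass is
    the autograd twin of :func:`nhcn_forward`, so gradients reach both the
    hyperedge embedding (the dynamic topology) and the category features.
    """

    def __init__(self, n_drugs: int, n_microbes: int, attr_width: int,
                 ne: int = 32, lhnn: int = 2, category_dim: int = 64,
                 leaky_slope: float = 0.01, use_category: bool = True,
                 rng: np.random.Generator | None = None,
                 init_scale: float = 0.1):
        rng = rng or np.random.default_rng(0)
        self.n_drugs = n_drugs
        self.n_microbes = n_microbes
        self.lhnn = lhnn
        self.leaky_slope = leaky_slope
        self.use_category = use_category
        # small positive init: with non-negative attributes, a hyperedge
        # whose incidence column clamps to zero at birth receives no
        # gradient and can never activate, so E starts in the open region
        self.E = Parameter(rng.uniform(0.0, 2.0 * init_scale, size=(attr_width, ne)))
        if use_category:
            cat = init_category_features(
                n_drugs, n_microbes, category_dim,
                seed=int(rng.integers(2**31)), scale=init_scale)
            self.Y = Parameter(cat.Y)
        else:
            self.Y = None

    def parameters(self) -> list[Parameter]:
        return [self.E] + ([self.Y] if self.Y is not None else [])

    @property
    def out_width(self) -> int:
        base = self.n_drugs + self.n_microbes
        return base + (self.Y.data.shape[1] if self.Y is not None else 0)

    def forward(self, Z: Tensor) -> Tensor:
        H = (Z @ self.E).relu()
        db_inv_sqrt = H.sum(axis=1).safe_pow(-0.5)
        de_inv = H.sum(axis=0).safe_pow(-1.0)
        Hn = H * db_inv_sqrt.reshape(-1, 1)
        Hn_scaled = Hn * de_inv.reshape(1, -1)
        X = concat([Z, self.Y], axis=1) if self.Y is not None else Z
        for _ in range(self.lhnn):
            X = (Hn_scaled @ (Hn.T @ X)).leaky_relu(self.leaky_slope)
        return X
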