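"""The full association-prediction model: NHCN + GCNFP + SCA + fusion head.

:class:`DhdmpModel` wires the three encoders and the conv-pool head into a
single trainable graph.  A forward pass takes the precomputed graph bundle
(attribute matrix and the two block adjacencies, all constants within a
fold) plus a batch of (drug, microbe) index pairs, and yields two-class
logits per pair.  Every component can be switched off for ablation; a
disabled component contributes a zero block of matching geometry to the
fusion stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor, concat
from .data_graph import GraphBundle
from .fusion_head import FusionHeadModule
from .gcnfp import GcnfpModule
from .nhcn import NhcnModule
from .sca import ScaModule

__all__ = ["ModelConfig", "DhdmpModel"]


@dataclass
class ModelConfig:
    """Hyperparameters of the model.

    Defaults follow the reference setting: 32 hyperedges, two encoding
    layers in both NHCN and GCNFP, patch size 50 with Ndim 50 and eight
    attention heads, conv kernels 2x10 / 1x10 with a 1x10 pooling window.
    Widths that the reference setting leaves open (category feature width,
    GCN hidden width, projection width, fused width, conv channels) have
    package defaults and are configurable.
    """

    ne: int = 32
    lhnn: int = 2
    category_dim: int = 64
    leaky_slope: float = 0.01
    lgcn: int = 2
    gcn_hidden: int = 256
    d_proj: int = 128
    alpha_init: float = 1.0
    patch_size: int = 50
    ndim: int = 50
    heads: int = 8
    d_fuse: int = 300
    conv_channels: tuple[int, int] = (8, 16)
    pool: int = 10
    loss_reduction: str = "mean"
    dtype: str = "float32"
    # ablation switches
    use_nhcn: bool = True
    use_gcnfp: bool = True
    use_sca: bool = True
    use_category: bool = True
    use_nfps: bool = True

    def ablation_label(self) -> str:
        off = [name for flag, name in (
            (self.use_nhcn, "NHCN"), (self.use_gcnfp, "GCNFP"),
            (self.use_sca, "SCA"), (self.use_category, "category"),
            (self.use_nfps, "NFPS")) if not flag]
        return "full" if not off else "without " + "+".join(off)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        cfg = ModelConfig(**d)
        if isinstance(cfg.conv_channels, list):
            cfg.conv_channels = tuple(cfg.conv_channels)
        return cfg


class DhdmpModel:
    """Joint trainable model over a fixed graph bundle."""

    def __init__(self, bundle: GraphBundle, config: ModelConfig | None = None,
                 seed: int = 0):
        self.config = cfg = config or ModelConfig()
        if not (cfg.use_nhcn or cfg.use_gcnfp or cfg.use_sca):
            raise ValueError("at least one encoder must be enabled")
        self.bundle = bundle
        nd, nm = bundle.n_drugs, bundle.n_microbes
        n = nd + nm
        self.n_drugs = nd
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.Z = Tensor(bundle.Z)
        self.Ahomo = Tensor(bundle.Ahomo)
        self.Ahete = Tensor(bundle.Ahete)

        self.nhcn = None
        if cfg.use_nhcn:
            self.nhcn = NhcnModule(
                nd, nm, attr_width=n, ne=cfg.ne, lhnn=cfg.lhnn,
                category_dim=cfg.category_dim, leaky_slope=cfg.leaky_slope,
                use_category=cfg.use_category, rng=rng)
        self.gcnfp = None
        if cfg.use_gcnfp:
            self.gcnfp = GcnfpModule(
                nd, nm, attr_width=n, lgcn=cfg.lgcn, hidden=cfg.gcn_hidden,
                d_proj=cfg.d_proj, use_nfps=cfg.use_nfps,
                alpha_init=cfg.alpha_init, rng=rng)
        self.sca = None
        self._node_patches = None
        if cfg.use_sca:
            self.sca = ScaModule(patch_size=cfg.patch_size, ndim=cfg.ndim,
                                 heads=cfg.heads, rng=rng)
            self._node_patches = self.sca.node_patches(bundle.Z)

        widths = {
            "mna": self.nhcn.out_width if self.nhcn else None,
            "hhn": cfg.d_proj if self.gcnfp else None,
            "lds": self.sca.out_width(n) if self.sca else None,
        }
        self.head = FusionHeadModule(
            widths, d_fuse=cfg.d_fuse, conv_channels=cfg.conv_channels,
            pool=cfg.pool, rng=rng)

        dt = np.dtype(cfg.dtype)
        if dt != np.float64:
            for p in self.parameters():
                p.data = p.data.astype(dt)
            for t in (self.Z, self.Ahomo, self.Ahete):
                t.data = t.data.astype(dt)
            if self._node_patches is not None:
                self._node_patches = self._node_patches.astype(dt)

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for mod in (self.nhcn, self.gcnfp, self.sca, self.head):
            if mod is not None:
                ps += mod.parameters()
        return ps

    def forward(self, drug_idx: np.ndarray, microbe_idx: np.ndarray) -> Tensor:
        """Logits (B, 2) for a batch of (drug, microbe) index pairs."""
        drug_idx = np.asarray(drug_idx, dtype=np.intp)
        microbe_idx = np.asarray(microbe_idx, dtype=np.intp)
        nd = self.n_drugs
        node_idx = np.stack([drug_idx, nd + microbe_idx], axis=1)  # (B, 2)
        blocks: dict[str, Tensor | None] = {"mna": None, "hhn": None, "lds": None}
        if self.nhcn is not None:
            Xt = self.nhcn.forward(self.Z)
            blocks["mna"] = Xt[node_idx]                  # (B, 2, w1)
        if self.gcnfp is not None:
            proj = self.gcnfp.forward(self.Z, self.Ahomo, self.Ahete)
            rows = [proj["homo"][drug_idx.reshape(-1, 1)],
                    proj["hete"][drug_idx.reshape(-1, 1)],
                    proj["homo"][(nd + microbe_idx).reshape(-1, 1)],
                    proj["hete"][(nd + microbe_idx).reshape(-1, 1)]]
            blocks["hhn"] = concat(rows, axis=1)          # (B, 4, d_proj)
        if self.sca is not None:
            dpat = Tensor(self._node_patches[drug_idx])
            mpat = Tensor(self._node_patches[nd + microbe_idx])
            blocks["lds"] = self.sca.forward(dpat, mpat)  # (B, 2, w3)
        return self.head.forward(blocks)

    def loss(self, drug_idx, microbe_idx, y) -> Tensor:
        logits = self.forward(drug_idx, microbe_idx)
        return self.head.loss(logits, y, reduction=self.config.loss_reduction)

    def predict_scores(self, drug_idx, microbe_idx, chunk: int = 256) -> np.ndarray:
        """Association probabilities p[1] for arbitrary pair lists (no grad)."""
        drug_idx = np.asarray(drug_idx)
        microbe_idx = np.asarray(microbe_idx)
        out = np.empty(len(drug_idx))
        for s in range(0, len(drug_idx), chunk):
            sl = slice(s, s + chunk)
            logits = self.forward(drug_idx[sl], microbe_idx[sl]).data
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            out[sl] = (e / e.sum(axis=1, keepdims=True))[:, 1]
        return out
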