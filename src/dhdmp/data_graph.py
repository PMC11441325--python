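"""Input matrices and graph construction for drug-microbe association prediction.

The raw inputs are three matrices: a binary drug-microbe association matrix
``R`` (Nd x Nm), a drug-drug structural similarity matrix ``Dstruct`` and a
microbe-microbe sequence similarity matrix ``Msim`` (both symmetric, entries
in [0, 1], unit diagonal).  From these we derive

* a Gaussian interaction-profile kernel similarity between drugs, computed
  from their association profiles,
* the fused drug similarity (average of structural and kernel similarity),
* the joint node attribute matrix ``Z = [[Dsim, R], [R^T, Msim]]``, whose
  i-th row is the attribute vector of node i,
* Laplacian-normalized adjacencies of the two homogeneous similarity graphs
  and the bipartite association graph, assembled into block matrices
  ``Ahomo`` (block-diagonal) and ``Ahete`` (off-diagonal blocks only).

The degree used for normalization is the *count of non-zero entries* of a
row, not the row sum; zero-degree rows map to all-zero rows (isolated nodes
exchange no messages).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "GraphBundle",
    "gaussian_kernel_similarity",
    "fuse_drug_similarity",
    "build_node_attributes",
    "laplacian_normalize",
    "bipartite_normalize",
    "assemble_block_adjacency",
    "build_graph_bundle",
    "load_dataset",
    "save_dataset",
    "save_bundle",
    "load_bundle",
]

_SYM_TOL = 1e-9


@dataclass
class AssociationDataset:
    """Raw inputs: associations plus the two similarity matrices.

    Attributes
    ----------
    R : (Nd, Nm) binary array, 1 = known drug-microbe association.
    Dstruct : (Nd, Nd) symmetric structural similarity, unit diagonal.
    Msim : (Nm, Nm) symmetric sequence similarity, unit diagonal.
    drug_ids, microbe_ids : identifier lists (metadata; matrix order is
        canonical).
    """

    R: np.ndarray
    Dstruct: np.ndarray
    Msim: np.ndarray
    drug_ids: list[str]
    microbe_ids: list[str]

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        self.Dstruct = np.asarray(self.Dstruct, dtype=np.float64)
        self.Msim = np.asarray(self.Msim, dtype=np.float64)
        self.validate()

    @property
    def n_drugs(self) -> int:
        return self.R.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.R.shape[1]

    @property
    def n_positives(self) -> int:
        return int(self.R.sum())

    def validate(self) -> None:
        nd, nm = self.R.shape
        bad = np.argwhere((self.R != 0) & (self.R != 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"association matrix must be binary; R[{i},{j}] = {self.R[i, j]!r}"
            )
        for name, m, n in (("Dstruct", self.Dstruct, nd), ("Msim", self.Msim, nm)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if np.abs(m - m.T).max() > _SYM_TOL:
                raise ValueError(f"{name} is not symmetric within {_SYM_TOL}")
            if np.abs(np.diag(m) - 1.0).max() > _SYM_TOL:
                raise ValueError(f"{name} must have unit diagonal")
            if m.min() < 0 or m.max() > 1 + _SYM_TOL:
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if len(self.drug_ids) != nd:
            raise ValueError(f"expected {nd} drug ids, got {len(self.drug_ids)}")
        if len(self.microbe_ids) != nm:
            raise ValueError(f"expected {nm} microbe ids, got {len(self.microbe_ids)}")


@dataclass
class GraphBundle:
    """Derived similarity, attribute, and adjacency structures."""

    Dsim: np.ndarray
    Dgauss: np.ndarray
    mu: float
    Z: np.ndarray
    Rdrg_norm: np.ndarray
    Rmic_norm: np.ndarray
    Rdm_norm: np.ndarray
    Ahomo: np.ndarray
    Ahete: np.ndarray
    n_drugs: int
    n_microbes: int


def gaussian_kernel_similarity(R: np.ndarray, mu_prime: float = 1.0):
    """Gaussian interaction-profile kernel similarity between drugs.

    ``Dgauss[i, j] = exp(-mu * ||R_i - R_j||^2)`` with the bandwidth
    normalized by the mean squared profile norm:
    ``mu = mu' / ((1/Nd) * sum_i ||R_i||^2)``.  The original bandwidth
    ``mu'`` defaults to 1.

    Returns
    -------
    (Dgauss, mu) : the Nd x Nd kernel matrix and the normalized bandwidth.
    """
    R = np.asarray(R, dtype=np.float64)
    nd = R.shape[0]
    norm_sq = (R**2).sum(axis=1)
    mean_norm = norm_sq.mean()
    if mean_norm == 0.0:
        raise ValueError(
            "all-zero association matrix: kernel bandwidth normalization "
            "divides by the mean squared profile norm, which is zero"
        )
    mu = mu_prime / mean_norm
    # ||R_i - R_j||^2 = ||R_i||^2 + ||R_j||^2 - 2 R_i.R_j
    sq_dist = norm_sq[:, None] + norm_sq[None, :] - 2.0 * (R @ R.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    d = np.exp(-mu * sq_dist)
    np.fill_diagonal(d, 1.0)
    return (d + d.T) / 2.0, float(mu)


def fuse_drug_similarity(Dstruct: np.ndarray, Dgauss: np.ndarray) -> np.ndarray:
    """Average of structural and Gaussian kernel similarity."""
    Dstruct = np.asarray(Dstruct, dtype=np.float64)
    Dgauss = np.asarray(Dgauss, dtype=np.float64)
    if Dstruct.shape != Dgauss.shape:
        raise ValueError(
            f"shape mismatch: Dstruct {Dstruct.shape} vs Dgauss {Dgauss.shape}"
        )
    return (Dstruct + Dgauss) / 2.0


def build_node_attributes(Dsim: np.ndarray, Msim: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Joint node attribute matrix ``Z = [[Dsim, R], [R^T, Msim]]``."""
    nd, nm = R.shape
    if Dsim.shape != (nd, nd) or Msim.shape != (nm, nm):
        raise ValueError("dimension mismatch among Dsim, Msim, R")
    return np.block([[Dsim, R], [R.T, Msim]])


def laplacian_normalize(M: np.ndarray) -> np.ndarray:
    """Symmetric normalization ``D^{-1/2} M D^{-1/2}``.

    ``D[i, i]`` is the number of non-zero entries in row i.  Rows/columns
    with zero degree come out all-zero (no non-finite values).
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if M.min() < 0:
        raise ValueError("adjacency entries must be non-negative")
    deg = np.count_nonzero(M, axis=1).astype(np.float64)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, deg**-0.5, 0.0)
    return d_inv_sqrt[:, None] * M * d_inv_sqrt[None, :]


def bipartite_normalize(R: np.ndarray) -> np.ndarray:
    """Normalize the bipartite association matrix via its square embedding.

    Embeds R in ``[[0, R], [R^T, 0]]``, applies :func:`laplacian_normalize`,
    and returns the off-diagonal block — equivalently
    ``Drow^{-1/2} R Dcol^{-1/2}`` with non-zero-count degrees.
    """
    nd, nm = R.shape
    big = np.zeros((nd + nm, nd + nm))
    big[:nd, nd:] = R
    big[nd:, :nd] = R.T
    return laplacian_normalize(big)[:nd, nd:]


def assemble_block_adjacency(Rdrg_norm, Rmic_norm, Rdm_norm):
    """Block matrices over the joint node set.

    ``Ahomo = blockdiag(Rdrg_norm, Rmic_norm)`` carries same-type
    (similarity) edges; ``Ahete = [[0, Rdm_norm], [Rdm_norm^T, 0]]`` carries
    cross-type (association) edges.
    """
    nd = Rdrg_norm.shape[0]
    nm = Rmic_norm.shape[0]
    if Rdrg_norm.shape != (nd, nd) or Rmic_norm.shape != (nm, nm):
        raise ValueError("homogeneous adjacencies must be square")
    if Rdm_norm.shape != (nd, nm):
        raise ValueError(
            f"bipartite adjacency must be {nd}x{nm}, got {Rdm_norm.shape}"
        )
    n = nd + nm
    ahomo = np.zeros((n, n))
    ahomo[:nd, :nd] = Rdrg_norm
    ahomo[nd:, nd:] = Rmic_norm
    ahete = np.zeros((n, n))
    ahete[:nd, nd:] = Rdm_norm
    ahete[nd:, :nd] = Rdm_norm.T
    return ahomo, ahete


def build_graph_bundle(dataset: AssociationDataset, R: np.ndarray | None = None,
                       mu_prime: float = 1.0) -> GraphBundle:
    """Construct every derived structure from a dataset.

    Parameters
    ----------
    R : optional override of the association matrix (e.g. the
        training-masked matrix during cross-validation, with held-out
        positives zeroed).  Defaults to ``dataset.R``.
    """
    if R is None:
        R = dataset.R
    dgauss, mu = gaussian_kernel_similarity(R, mu_prime=mu_prime)
    dsim = fuse_drug_similarity(dataset.Dstruct, dgauss)
    z = build_node_attributes(dsim, dataset.Msim, R)
    rdrg = laplacian_normalize(dsim)
    rmic = laplacian_normalize(dataset.Msim)
    rdm = bipartite_normalize(R)
    ahomo, ahete = assemble_block_adjacency(rdrg, rmic, rdm)
    return GraphBundle(
        Dsim=dsim, Dgauss=dgauss, mu=mu, Z=z,
        Rdrg_norm=rdrg, Rmic_norm=rmic, Rdm_norm=rdm,
        Ahomo=ahomo, Ahete=ahete,
        n_drugs=dataset.n_drugs, n_microbes=dataset.n_microbes,
    )


# ---------------------------------------------------------------------------
# I/O: delimited-text matrices with identifier sidecars, HDF5 bundle.
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> np.ndarray:
    """Read a TSV/CSV matrix, tolerating an optional header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not np.issubdtype(first.dtypes.iloc[-1], np.number)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    try:
        return df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc


def _read_ids(path: Path | None, n: int, prefix: str) -> list[str]:
    if path is None:
        return [f"{prefix}{i}" for i in range(n)]
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(ids) != n:
        raise ValueError(f"{path}: expected {n} identifiers, found {len(ids)}")
    return ids


def load_dataset(assoc: Path, drug_sim: Path, microbe_sim: Path,
                 drug_ids: Path | None = None,
                 microbe_ids: Path | None = None) -> AssociationDataset:
    """Load and validate the three input matrices (TSV/CSV + id sidecars)."""
    R = _read_matrix(assoc)
    dstruct = _read_matrix(drug_sim)
    msim = _read_matrix(microbe_sim)
    nd, nm = R.shape
    return AssociationDataset(
        R=R, Dstruct=dstruct, Msim=msim,
        drug_ids=_read_ids(drug_ids, nd, "drug_"),
        microbe_ids=_read_ids(microbe_ids, nm, "microbe_"),
    )


def save_dataset(dataset: AssociationDataset, out_dir: Path) -> dict[str, Path]:
    """Write a dataset as TSV matrices plus identifier sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assoc": out_dir / "associations.tsv",
        "drug_sim": out_dir / "drug_similarity.tsv",
        "microbe_sim": out_dir / "microbe_similarity.tsv",
        "drug_ids": out_dir / "drug_ids.txt",
        "microbe_ids": out_dir / "microbe_ids.txt",
    }
    np.savetxt(paths["assoc"], dataset.R, fmt="%d", delimiter="\t")
    np.savetxt(paths["drug_sim"], dataset.Dstruct, fmt="%.12g", delimiter="\t")
    np.savetxt(paths["microbe_sim"], dataset.Msim, fmt="%.12g", delimiter="\t")
    paths["drug_ids"].write_text("\n".join(dataset.drug_ids) + "\n")
    paths["microbe_ids"].write_text("\n".join(dataset.microbe_ids) + "\n")
    return paths


def save_bundle(bundle: GraphBundle, path: Path) -> None:
    """Write a :class:`GraphBundle` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for name in ("Dsim", "Dgauss", "Z", "Rdrg_norm", "Rmic_norm",
                     "Rdm_norm", "Ahomo", "Ahete"):
            f.create_dataset(name, data=getattr(bundle, name))
        f.attrs["mu"] = bundle.mu
        f.attrs["n_drugs"] = bundle.n_drugs
        f.attrs["n_microbes"] = bundle.n_microbes


def load_bundle(path: Path) -> GraphBundle:
    with h5py.File(path, "r") as f:
        arrays = {name: f[name][()] for name in
                  ("Dsim", "Dgauss", "Z", "Rdrg_norm", "Rmic_norm",
                   "Rdm_norm", "Ahomo", "Ahete")}
        return GraphBundle(
            mu=float(f.attrs["mu"]),
            n_drugs=int(f.attrs["n_drugs"]),
            n_microbes=int(f.attrs["n_microbes"]),
            **arrays,
        )
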