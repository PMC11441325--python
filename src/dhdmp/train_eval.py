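"""Training loop, five-fold cross-validation, and evaluation metrics.

Protocol: all known associations (positives) are shuffled and divided into
five equal parts (remainder round-robin).  Per fold, the training set is
the other four parts plus an equal number of negatives sampled uniformly
without replacement from the unknown pairs; the test set is the held-out
positives plus *all* remaining unknown pairs (so precision-recall baselines
are low, as in the heavily imbalanced real setting).  The graph bundle for
a fold is rebuilt from the training-masked association matrix — held-out
positives are zeroed — so no test pair influences training, not even
through node attributes.

Metrics: fold-wise AUC and AUPR (averaged over folds), and per-drug
recall@k (fraction of a drug's test positives ranked in its top k
candidates, averaged over drugs with at least one test positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_graph import AssociationDataset, build_graph_bundle
from .autograd import Adam
from .model import DhdmpModel, ModelConfig

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "EvalResult",
    "five_fold_split",
    "train_model",
    "compute_auc",
    "compute_aupr",
    "per_drug_metrics",
    "topk_recall",
    "run_cv",
    "ablation_grid",
    "run_ablation_grid",
]


@dataclass
class TrainConfig:
    """Optimization settings: Adam, 80 epochs, batch 32, lr 5e-4 by default."""

    epochs: int = 80
    batch_size: int = 32
    lr: float = 5e-4
    weight_decay: float = 0.02
    seed: int = 0


@dataclass
class FoldSplit:
    """Index arrays (flattened pair ids = drug * Nm + microbe) for one fold."""

    fold_id: int
    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray

    @property
    def train_pairs(self) -> np.ndarray:
        return np.concatenate([self.train_pos, self.train_neg])

    @property
    def train_labels(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.train_pos)), np.zeros(len(self.train_neg))])

    @property
    def test_pairs(self) -> np.ndarray:
        return np.concatenate([self.test_pos, self.test_neg])

    @property
    def test_labels(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.test_pos)), np.zeros(len(self.test_neg))])


@dataclass
class EvalResult:
    """Cross-validation outcome.

    ``auc``/``aupr`` are fold-level metrics averaged over folds;
    ``per_drug`` tabulates within-drug AUC/AUPR for every evaluated drug
    (those with at least one test positive and one test negative).
    """

    fold_metrics: pd.DataFrame
    auc: float
    aupr: float
    recall_at_k: pd.DataFrame
    per_drug: pd.DataFrame | None = None
    history: list[list[float]] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)


def five_fold_split(R: np.ndarray, seed: int, n_folds: int = 5) -> list[FoldSplit]:
    """Partition positives into folds and sample balanced training negatives.

    Test negatives of a fold are every unknown pair not sampled as a
    training negative for that fold.
    """
    R = np.asarray(R)
    nd, nm = R.shape
    pos = np.flatnonzero(R.ravel() == 1)
    neg = np.flatnonzero(R.ravel() == 0)
    if len(pos) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, got {len(pos)}")
    ss = np.random.SeedSequence(seed)
    rng_shuffle, rng_neg = [np.random.default_rng(s) for s in ss.spawn(2)]
    perm = rng_shuffle.permutation(pos)
    parts = [perm[k::n_folds] for k in range(n_folds)]  # round-robin remainder
    folds = []
    for k in range(n_folds):
        test_pos = np.sort(parts[k])
        train_pos = np.sort(np.concatenate([parts[i] for i in range(n_folds) if i != k]))
        train_neg = np.sort(rng_neg.choice(neg, size=len(train_pos), replace=False))
        test_neg = np.sort(np.setdiff1d(neg, train_neg, assume_unique=True))
        folds.append(FoldSplit(k + 1, train_pos, train_neg, test_pos, test_neg))
    return folds


def _unravel(pair_ids: np.ndarray, nm: int):
    return pair_ids // nm, pair_ids % nm


def train_model(model: DhdmpModel, train_pairs: np.ndarray, labels: np.ndarray,
                nm: int, train_cfg: TrainConfig) -> list[float]:
    """Minibatch Adam training; returns per-epoch mean loss."""
    opt = Adam(model.parameters(), lr=train_cfg.lr,
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence(train_cfg.seed))
    labels = np.asarray(labels, dtype=np.float64)
    history = []
    n = len(train_pairs)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, train_cfg.batch_size):
            batch = order[s: s + train_cfg.batch_size]
            di, mi = _unravel(train_pairs[batch], nm)
            opt.zero_grad()
            loss = model.loss(di, mi, labels[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch + 1}, batch starting at "
                    f"sample {s}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return history


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def compute_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR requires both classes present")
    return float(average_precision_score(labels, scores))


def per_drug_metrics(scores: np.ndarray, labels: np.ndarray,
                     drug_of_pair: np.ndarray) -> pd.DataFrame:
    """Within-drug AUC and AUPR for drugs whose test candidates contain
    both classes."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    drug_of_pair = np.asarray(drug_of_pair)
    rows = []
    for d in np.unique(drug_of_pair):
        mask = drug_of_pair == d
        lab = labels[mask]
        if 0 < lab.sum() < mask.sum():
            rows.append({"drug": int(d),
                         "n_test_pos": int(lab.sum()),
                         "auc": compute_auc(scores[mask], lab),
                         "aupr": compute_aupr(scores[mask], lab)})
    return pd.DataFrame(rows)


def topk_recall(scores: np.ndarray, labels: np.ndarray, drug_of_pair: np.ndarray,
                k_list: list[int]) -> pd.DataFrame:
    """Per-drug recall@k, averaged over drugs with >= 1 test positive.

    Ties are broken by stable pair order.  Returns a table with one row per
    evaluated drug plus a final ``average`` row.
    """
    if len(scores) == 0:
        raise ValueError("empty ranking")
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    drug_of_pair = np.asarray(drug_of_pair)
    rows = []
    for d in np.unique(drug_of_pair):
        mask = drug_of_pair == d
        lab = labels[mask]
        npos = int(lab.sum())
        if npos == 0:
            continue
        order = np.argsort(-scores[mask], kind="stable")
        ranked = lab[order]
        rows.append({"drug": int(d), "n_test_pos": npos,
                     **{f"recall@{k}": float(ranked[:k].sum() / npos)
                        for k in k_list}})
    df = pd.DataFrame(rows)
    avg = {"drug": "average", "n_test_pos": int(df["n_test_pos"].sum()),
           **{f"recall@{k}": float(df[f"recall@{k}"].mean()) for k in k_list}}
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def run_cv(dataset: AssociationDataset, model_cfg: ModelConfig | None = None,
           train_cfg: TrainConfig | None = None, seed: int = 0,
           k_list: list[int] | None = None, n_folds: int = 5) -> EvalResult:
    """Five-fold cross-validation of the full pipeline.

    Per fold: mask the held-out positives out of R, rebuild the graph
    bundle, train a fresh model, score the fold's test pairs, and compute
    AUC/AUPR and per-drug recall@k.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    k_list = k_list or [1, 3, 5, 10]
    nd, nm = dataset.R.shape
    ss = np.random.SeedSequence(seed)
    split_seed, *fold_seeds = [int(s.generate_state(1)[0] % 2**31)
                               for s in ss.spawn(n_folds + 1)]
    folds = five_fold_split(dataset.R, seed=split_seed, n_folds=n_folds)
    rows, histories, recall_frames, per_drug_frames = [], [], [], []
    for fold, fseed in zip(folds, fold_seeds):
        assert np.intersect1d(fold.train_pairs, fold.test_pairs).size == 0
        R_train = dataset.R.copy().ravel()
        R_train[fold.test_pos] = 0.0
        R_train = R_train.reshape(nd, nm)
        bundle = build_graph_bundle(dataset, R=R_train)
        model = DhdmpModel(bundle, model_cfg, seed=fseed)
        fold_train = TrainConfig(epochs=train_cfg.epochs,
                                 batch_size=train_cfg.batch_size,
                                 lr=train_cfg.lr,
                                 weight_decay=train_cfg.weight_decay,
                                 seed=fseed)
        history = train_model(model, fold.train_pairs, fold.train_labels,
                              nm, fold_train)
        di, mi = _unravel(fold.test_pairs, nm)
        scores = model.predict_scores(di, mi)
        labels = fold.test_labels
        rows.append({"fold": fold.fold_id,
                     "auc": compute_auc(scores, labels),
                     "aupr": compute_aupr(scores, labels)})
        recall_frames.append(topk_recall(scores, labels, di, k_list))
        per_drug_frames.append(per_drug_metrics(scores, labels, di)
                               .assign(fold=fold.fold_id))
        histories.append(history)
    fold_metrics = pd.DataFrame(rows)
    # collect each fold's drug-averaged recall row, then average over folds
    per_fold = pd.DataFrame([
        {"fold": fold.fold_id,
         **{f"recall@{k}": float(frame.iloc[-1][f"recall@{k}"]) for k in k_list}}
        for fold, frame in zip(folds, recall_frames)])
    avg_row = {"fold": "average",
               **{f"recall@{k}": float(per_fold[f"recall@{k}"].mean())
                  for k in k_list}}
    recall_table = pd.concat([per_fold, pd.DataFrame([avg_row])],
                             ignore_index=True)
    return EvalResult(
        fold_metrics=fold_metrics,
        auc=float(fold_metrics["auc"].mean()),
        aupr=float(fold_metrics["aupr"].mean()),
        recall_at_k=recall_table,
        per_drug=pd.concat(per_drug_frames, ignore_index=True),
        history=histories,
        seeds={"master": seed, "split": split_seed, "folds": fold_seeds},
    )


def ablation_grid() -> list[ModelConfig]:
    """The six ablation configurations.

    Removing NHCN also removes the category features (they live in NHCN);
    removing GCNFP also removes NFPS (it scales the GCNFP injection).
    """
    return [
        ModelConfig(use_nhcn=False, use_category=False),
        ModelConfig(use_gcnfp=False, use_nfps=False),
        ModelConfig(use_sca=False),
        ModelConfig(use_category=False),
        ModelConfig(use_nfps=False),
        ModelConfig(),
    ]


def run_ablation_grid(dataset: AssociationDataset,
                      train_cfg: TrainConfig | None = None,
                      seed: int = 0, n_folds: int = 5) -> pd.DataFrame:
    """Run every ablation configuration and tabulate average AUC/AUPR."""
    rows = []
    for cfg in ablation_grid():
        res = run_cv(dataset, cfg, train_cfg, seed=seed, n_folds=n_folds)
        rows.append({
            "NHCN": cfg.use_nhcn, "GCNFP": cfg.use_gcnfp, "SCA": cfg.use_sca,
            "category": cfg.use_category, "NFPS": cfg.use_nfps,
            "label": cfg.ablation_label(),
            "auc": res.auc, "aupr": res.aupr,
        })
    return pd.DataFrame(rows)
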