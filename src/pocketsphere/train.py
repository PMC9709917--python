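"""Training loops, data splitting, and similarity evaluation.

Two objectives share the spherical CNN trunk:

* **classify** — 3-way softmax + cross-entropy over ligand classes, Adam with
  learning rate 0.05 decayed by 0.1 every 25 epochs, batch 32, stratified
  k-fold cross-validation, per-sample random-rotation augmentation.
* **metric** — 256-d descriptors trained with the contrastive margin loss
  (m = 1.0), Adam with learning rate 5e-4, batch 128 pairs, at most 25,000
  randomly selected training pairs per epoch, rotations applied to both pair
  members; similarity of two pockets is the Euclidean distance between their
  descriptors, and pair retrieval is scored by ROC AUC.

Structures sharing more than 30% sequence identity belong to one cluster and
are assigned to the same side of any train/test split to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, squareform
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .healpix import healpix_sampling
from .maps import random_rotation, rotate_maps, SphericalMaps
from .nn import Adam, NetworkConfig, SphereCNN, contrastive_loss, cross_entropy

__all__ = [
    "TrainConfig", "PairRecord", "train_classifier", "train_metric",
    "sequence_cluster_split", "evaluate_roc", "pairwise_distances",
    "hierarchical_cluster", "kmer_identity_matrix",
]

log = logging.getLogger("pocketsphere")


@dataclass
class TrainConfig:
    """Hyperparameters for either objective (defaults per constructor)."""

    objective: str = "classify"
    lr: float = 0.05
    weight_decay: float = 0.0
    betas: tuple = (0.9, 0.999)
    batch_size: int = 32
    epochs: int = 60
    lr_step_epochs: int = 25
    lr_step_factor: float = 0.1
    margin: float = 1.0
    pairs_per_epoch: int = 25_000
    seed: int = 0
    folds: int = 5
    augment: bool = True
    n_side: int = 16
    channels: tuple = (32, 64, 128, 256)

    @classmethod
    def classify(cls, **kw) -> "TrainConfig":
        return replace(cls(), objective="classify", **kw)

    @classmethod
    def metric(cls, **kw) -> "TrainConfig":
        base = cls(objective="metric", lr=0.0005, batch_size=128, epochs=50)
        return replace(base, **kw)

    def lr_at(self, epoch: int) -> float:
        """Stepped decay; ``epoch`` is 1-based (epoch 26 with step 25 is one
        decay down)."""
        return self.lr * self.lr_step_factor ** ((epoch - 1) // self.lr_step_epochs)


@dataclass
class PairRecord:
    id_a: int
    id_b: int
    label: int  # 1 similar, 0 dissimilar

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("pair members must differ")
        if self.label not in (0, 1):
            raise ValueError("pair label must be 0 or 1")


def _as_stack(maps) -> np.ndarray:
    """(N, 9, n_pix) float array from a list of SphericalMaps or an array."""
    if isinstance(maps, np.ndarray):
        return maps
    return np.stack([m.channels for m in maps])


def _augment_batch(x: np.ndarray, grid, rng) -> np.ndarray:
    """Per-sample random-rotation augmentation by map resampling."""
    out = np.empty_like(x)
    for i in range(len(x)):
        R = random_rotation(rng)
        m = SphericalMaps(x[i], np.zeros(x.shape[2], bool), grid.n_side)
        out[i] = rotate_maps(m, R, grid).channels
    return out


def _run_classifier_epochs(model, opt, x, y_onehot, cfg, grid, rng):
    losses = []
    n = len(x)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s0 in range(0, n, cfg.batch_size):
            idx = order[s0:s0 + cfg.batch_size]
            xb = _augment_batch(x[idx], grid, rng) if cfg.augment else x[idx]
            p = model.forward(xb, train=True)
            loss = cross_entropy(p, y_onehot[idx])
            model.zero_grad()
            model.backward((p - y_onehot[idx]) / len(idx))
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
        log.info("classify epoch %d lr %.4g loss %.4f", epoch, opt.lr, losses[-1])
    return losses


def train_classifier(maps, labels, cfg: TrainConfig | None = None,
                     max_folds: int | None = None):
    """Stratified k-fold cross-validated classifier training.

    Returns a dict with per-fold models, loss curves, training/held-out
    accuracy, per-class one-vs-rest AUC, and their cross-fold means.
    ``max_folds`` trains only the first folds of the k-fold plan (sanity runs).
    """
    cfg = cfg or TrainConfig.classify()
    x = _as_stack(maps)
    y = np.asarray(labels, int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n_classes = len(classes)
    y_idx = np.searchsorted(classes, y)
    grid = healpix_sampling(cfg.n_side)

    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    folds = []
    for fold_i, (tr, te) in enumerate(skf.split(x, y_idx)):
        if max_folds is not None and fold_i >= max_folds:
            break
        if len(np.unique(y_idx[tr])) < n_classes or len(np.unique(y_idx[te])) < n_classes:
            raise ValueError(f"class missing from fold {fold_i}")
        rng = np.random.default_rng(cfg.seed * 10_000 + fold_i)
        net_cfg = NetworkConfig(n_side=cfg.n_side, channels=cfg.channels,
                                head="classifier", n_classes=n_classes)
        model = SphereCNN(net_cfg, seed=cfg.seed * 10_000 + fold_i)
        opt = Adam(model, lr=cfg.lr, betas=cfg.betas,
                   weight_decay=cfg.weight_decay)
        onehot = np.eye(n_classes)[y_idx]
        losses = _run_classifier_epochs(model, opt, x[tr], onehot[tr], cfg, grid, rng)

        p_tr = model.forward(x[tr], train=False)
        p_te = model.forward(x[te], train=False)
        train_acc = float((p_tr.argmax(1) == y_idx[tr]).mean())
        test_acc = float((p_te.argmax(1) == y_idx[te]).mean())
        aucs = {int(classes[c]): float(roc_auc_score(y_idx[te] == c, p_te[:, c]))
                for c in range(n_classes)}
        folds.append({"model": model, "losses": losses, "train_accuracy": train_acc,
                      "test_accuracy": test_acc, "auc": aucs,
                      "train_idx": tr, "test_idx": te})
    return {
        "folds": folds,
        "mean_train_accuracy": float(np.mean([f["train_accuracy"] for f in folds])),
        "mean_test_accuracy": float(np.mean([f["test_accuracy"] for f in folds])),
        "mean_auc": {int(c): float(np.mean([f["auc"][int(c)] for f in folds]))
                     for c in classes},
    }


def _validate_pairs(pairs, n_items):
    for p in pairs:
        if not (0 <= p.id_a < n_items and 0 <= p.id_b < n_items):
            raise KeyError(f"pair ({p.id_a}, {p.id_b}) references a missing pocket id")


def train_metric(maps, pairs, cfg: TrainConfig | None = None,
                 split=None):
    """Contrastive metric learning on pocket pairs.

    ``split`` assigns every pocket to 'train' or 'test' (boolean array,
    True = test).  Pairs crossing the split are excluded (count logged).
    Returns the trained model, per-epoch losses, and test ROC/AUC where pairs
    are scored by negative descriptor distance.
    """
    cfg = cfg or TrainConfig.metric()
    x = _as_stack(maps)
    n = len(x)
    pairs = [p if isinstance(p, PairRecord) else PairRecord(*p) for p in pairs]
    _validate_pairs(pairs, n)
    if split is None:
        split = np.zeros(n, bool)
    is_test = np.asarray(split, bool)

    def side(p):
        a, b = is_test[p.id_a], is_test[p.id_b]
        return "cross" if a != b else ("test" if a else "train")

    train_pairs = [p for p in pairs if side(p) == "train"]
    test_pairs = [p for p in pairs if side(p) == "test"]
    n_cross = sum(side(p) == "cross" for p in pairs)
    if n_cross:
        log.info("excluded %d pairs crossing the train/test split", n_cross)
    if not train_pairs:
        raise ValueError("no training pairs after split filtering")

    grid = healpix_sampling(cfg.n_side)
    net_cfg = NetworkConfig(n_side=cfg.n_side, channels=cfg.channels,
                            head="embedder")
    model = SphereCNN(net_cfg, seed=cfg.seed)
    opt = Adam(model, lr=cfg.lr, betas=cfg.betas, weight_decay=cfg.weight_decay)

    master = np.random.default_rng(cfg.seed)
    losses = []
    for epoch in range(1, cfg.epochs + 1):
        rng = np.random.default_rng(master.integers(2**31))
        opt.lr = cfg.lr_at(epoch)
        sel = rng.permutation(len(train_pairs))[: cfg.pairs_per_epoch]
        epoch_loss, n_seen = 0.0, 0
        for s0 in range(0, len(sel), cfg.batch_size):
            batch = [train_pairs[i] for i in sel[s0:s0 + cfg.batch_size]]
            ia = np.array([p.id_a for p in batch])
            ib = np.array([p.id_b for p in batch])
            yb = np.array([p.label for p in batch], float)
            xb = np.concatenate([x[ia], x[ib]])
            if cfg.augment:
                xb = _augment_batch(xb, grid, rng)
            f = model.forward(xb, train=True)
            f1, f2 = f[: len(batch)], f[len(batch):]
            loss, g1, g2 = contrastive_loss(f1, f2, yb, m=cfg.margin)
            model.zero_grad()
            model.backward(np.concatenate([g1, g2]))
            opt.step()
            epoch_loss += loss * len(batch)
            n_seen += len(batch)
        losses.append(epoch_loss / n_seen)
        log.info("metric epoch %d lr %.4g loss %.4f", epoch, opt.lr, losses[-1])

    result = {"model": model, "losses": losses,
              "n_train_pairs": len(train_pairs), "n_cross_pairs": n_cross}
    if test_pairs:
        desc = model.embed(x)
        d = np.linalg.norm(
            desc[[p.id_a for p in test_pairs]] - desc[[p.id_b for p in test_pairs]],
            axis=1)
        labels = np.array([p.label for p in test_pairs])
        result["n_test_pairs"] = len(test_pairs)
        if len(np.unique(labels)) == 2:
            curve, auc = evaluate_roc(-d, labels)
            result.update({"test_auc": auc, "roc_curve": curve})
        else:
            log.info("test pairs are single-class; AUC not defined")
    return result


def sequence_cluster_split(identity: np.ndarray, threshold: float = 0.30,
                           seed: int = 0, test_fraction: float = 0.3) -> np.ndarray:
    """Cluster-respecting random train/test assignment.

    Single-linkage connected components of the graph ``identity > threshold``
    are whole-cluster assigned to the test side at random until the requested
    test fraction is reached.  Returns a boolean array, True = test.
    """
    identity = np.asarray(identity, float)
    if identity.ndim != 2 or identity.shape[0] != identity.shape[1]:
        raise ValueError("identity must be a square matrix")
    if not np.allclose(identity, identity.T, atol=1e-9):
        raise ValueError("identity matrix must be symmetric")
    n = len(identity)
    adj = coo_matrix(identity > threshold)
    _, comp = connected_components(adj, directed=False)
    rng = np.random.default_rng(seed)
    cluster_ids = rng.permutation(np.unique(comp))
    is_test = np.zeros(n, bool)
    target = test_fraction * n
    for cid in cluster_ids:
        if is_test.sum() >= target:
            break
        is_test[comp == cid] = True
    return is_test


def evaluate_roc(scores, labels):
    """ROC curve and AUC; AUC equals the Mann-Whitney probability that a
    random positive outscores a random negative (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return (fpr, tpr, thr), float(roc_auc_score(labels, scores))


def pairwise_distances(descriptors) -> np.ndarray:
    """Symmetric Euclidean distance matrix between descriptor vectors."""
    f = np.asarray(descriptors, float)
    if f.ndim != 2:
        raise ValueError("descriptors must be a (n, dim) array")
    D = cdist(f, f)
    np.fill_diagonal(D, 0.0)
    return D


def hierarchical_cluster(D: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) from a distance
    matrix; average linkage by default, deterministic index tie-break."""
    D = np.asarray(D, float)
    return linkage(squareform(D, checks=False), method=method)


def kmer_identity_matrix(sequences, k: int = 3) -> np.ndarray:
    """Fallback fractional sequence identity without an aligner: shared k-mer
    fraction |kmers(a) & kmers(b)| / min(|kmers(a)|, |kmers(b)|)."""
    sets = [set(s[i:i + k] for i in range(len(s) - k + 1)) for s in sequences]
    n = len(sets)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            out[i, j] = out[j, i] = len(sets[i] & sets[j]) / denom
    return out
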