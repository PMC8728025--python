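"""Three-layer classifier with a joint clustering objective and L2,1 sparsity.

The network maps Z-scaled expression through a single sigmoid hidden layer to
one sigmoid output node separating the two termini of the disease continuum.
Training minimizes

    L = BCE(p, y) + (alpha/2) * mean_i ||h_i - c_{a_i}||^2
        + lambda * sum_g ||W1[g, :]||_2

in two phases: an initialization phase without the clustering term, then a
joint phase where k-means centroids over the hidden representation are
refreshed periodically.  The row-wise L2,1 penalty drives whole gene rows of
the first-layer weight matrix toward zero, so the per-gene row norm (RSS)
doubles as a feature-importance score.

The smooth terms are optimized with Adam; the non-smooth L2,1 term is
handled by a proximal step (row-wise group soft-threshold) whose step size
is the Adam-preconditioned learning rate, in the style of proximal
preconditioned optimizers for group-regularized networks.  Applying the
penalty proximally rather than as a subgradient inside Adam keeps its
shrinkage deterministic: a subgradient fed through Adam's second-moment
normalizer is drowned whenever other loss terms contribute gradient
variance, and the weight distribution never bifurcates.  For the joint
phase the proximal preconditioner is frozen at its end-of-initialization
value and the learning rate is dropped (``joint_lr_factor``), so cluster
refinement fine-tunes the representation without erasing the group-sparse
structure established during initialization.

Everything runs in plain numpy: the network is tiny, and this keeps runs
single-threaded and bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

CLIP_LO = 1e-9
CLIP_HI = 1.0 - 1e-9

#: default hyperparameter grid for cross_validate, centred on the
#: cross-validated optimum (K=2, alpha=2, lambda=0.004)
DEFAULT_CV_GRID = [
    (K, alpha, lambda_)
    for K in (2, 3, 4)
    for alpha in (1.0, 2.0, 4.0)
    for lambda_ in (0.001, 0.004, 0.016)
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the staging network.

    Defaults follow the cross-validated optimum for the staging problem
    (K=2 clusters, clustering trade-off alpha=2, sparsity weight
    lambda=0.004) with Adam at learning rate 1e-4, 1500 initialization +
    5000 joint epochs, batch size 256 and 128 hidden nodes.
    """

    K: int = 2
    alpha: float = 2.0
    lambda_: float = 0.004
    learning_rate: float = 1e-4
    epochs_init: int = 1500
    epochs_joint: int = 5000
    batch_size: int = 256
    n_hidden: int = 128
    seed: int = 0
    cluster_update_interval: int = 10
    #: joint-phase learning-rate multiplier (fine-tuning schedule)
    joint_lr_factor: float = 0.1

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha < 0 or self.lambda_ < 0:
            raise ValueError("alpha and lambda must be nonnegative")


@dataclass
class NetworkParams:
    W1: np.ndarray  # n_genes x n_hidden
    B1: np.ndarray  # n_hidden
    W2: np.ndarray  # n_hidden x 1
    B2: np.ndarray  # 1

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W1.copy(), self.B1.copy(),
                             self.W2.copy(), self.B2.copy())


@dataclass
class ClusterState:
    centroids: np.ndarray   # K x n_hidden
    assignments: np.ndarray  # per-sample cluster index
    inertia: float


def init_network(n_genes: int, n_hidden: int, n_out: int = 1,
                 seed: int = 0) -> NetworkParams:
    """Gaussian fan-in initialization: W ~ N(0, 1/n_in), biases zero."""
    if min(n_genes, n_hidden, n_out) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    return NetworkParams(
        W1=rng.normal(0.0, 1.0 / np.sqrt(n_genes), size=(n_genes, n_hidden)),
        B1=np.zeros(n_hidden),
        W2=rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_hidden, n_out)),
        B2=np.zeros(n_out),
    )


def forward_hidden(params: NetworkParams, scaled: np.ndarray) -> np.ndarray:
    """Hidden activations for samples x genes input, clipped into
    [1e-9, 1 - 1e-9] so downstream logs never see exact 0 or 1."""
    scaled = np.asarray(scaled, dtype=float)
    if scaled.shape[1] != params.W1.shape[0]:
        raise ValueError("input gene dimension does not match W1; "
                         "check gene order")
    h = expit(scaled @ params.W1 + params.B1)
    return np.clip(h, CLIP_LO, CLIP_HI)


def forward_output(params: NetworkParams, hidden: np.ndarray) -> np.ndarray:
    """Per-sample class probability p(AD); predicted AD iff p >= 0.5."""
    p = expit(hidden @ params.W2 + params.B2)[:, 0]
    return np.clip(p, CLIP_LO, CLIP_HI)


def l21_norm(W1: np.ndarray) -> float:
    return float(np.sqrt((W1 ** 2).sum(axis=1)).sum())


def compute_loss(params: NetworkParams, scaled: np.ndarray, labels: np.ndarray,
                 clusters: Optional[ClusterState], alpha: float,
                 lambda_: float) -> Dict[str, float]:
    """Loss components at the given parameters (cluster term 0 in phase 1)."""
    h = forward_hidden(params, scaled)
    p = forward_output(params, h)
    y = np.asarray(labels, dtype=float)
    bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if clusters is not None and alpha > 0:
        diff = h - clusters.centroids[clusters.assignments]
        cluster = float(alpha / 2.0 * np.mean((diff ** 2).sum(axis=1)))
    else:
        cluster = 0.0
    sparsity = float(lambda_ * l21_norm(params.W1))
    return {"bce": bce, "cluster": cluster, "sparsity": sparsity,
            "total": bce + cluster + sparsity}


def update_clusters(hidden: np.ndarray, K: int, seed: int = 0) -> ClusterState:
    """K-means on the hidden representation (k-means++, 10 restarts)."""
    hidden = np.asarray(hidden)
    if K > hidden.shape[0]:
        raise ValueError("K exceeds number of samples")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    assignments = km.fit_predict(hidden)
    return ClusterState(km.cluster_centers_, assignments, float(km.inertia_))


class _ProxAdam:
    """Adam on the smooth loss + proximal group soft-threshold on W1 rows.

    The proximal step size for gene row g is lr / mean_j sqrt(vhat[g, j]),
    i.e. the Adam-preconditioned learning rate averaged over the row.  The
    preconditioner can be frozen (``freeze_preconditioner``) so later
    high-variance phases do not weaken the penalty.  A row shrunk to zero
    stays at exactly zero until the data gradient revives it.
    """

    def __init__(self, shapes, lr, lambda_, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.lambda_ = lambda_
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self._frozen_eta: Optional[np.ndarray] = None

    def _row_eta(self) -> np.ndarray:
        vhat = np.sqrt(self.v[0] / (1 - self.b2 ** self.t)) + self.eps
        return 1.0 / vhat.mean(axis=1)

    def freeze_preconditioner(self) -> None:
        if self.t > 0:
            self._frozen_eta = self._row_eta()

    def step(self, params: List[np.ndarray], grads: List[np.ndarray],
             lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
        if self.lambda_ > 0:
            eta = self._frozen_eta if self._frozen_eta is not None \
                else self._row_eta()
            W1 = params[0]
            norms = np.sqrt((W1 ** 2).sum(axis=1))
            shrink = np.maximum(
                0.0, 1.0 - lr * eta * self.lambda_ / np.maximum(norms, 1e-12))
            W1 *= shrink[:, None]


def _gradients(params: NetworkParams, X: np.ndarray, y: np.ndarray,
               centroids: Optional[np.ndarray],
               assignments: Optional[np.ndarray],
               alpha: float) -> List[np.ndarray]:
    """Backprop of the smooth loss terms for one mini-batch; the output
    clipping is treated as straight-through."""
    n = X.shape[0]
    z1 = X @ params.W1 + params.B1
    h = np.clip(expit(z1), CLIP_LO, CLIP_HI)
    p = np.clip(expit(h @ params.W2 + params.B2)[:, 0], CLIP_LO, CLIP_HI)

    dz2 = (p - y)[:, None] / n                      # d bce / d z2
    gW2 = h.T @ dz2
    gB2 = dz2.sum(axis=0)

    dh = dz2 @ params.W2.T
    if centroids is not None and alpha > 0:
        dh = dh + alpha * (h - centroids[assignments]) / n
    dz1 = dh * h * (1.0 - h)
    gW1 = X.T @ dz1
    gB1 = dz1.sum(axis=0)
    return [gW1, gB1, gW2, gB2]


def _accuracy(params: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    p = forward_output(params, forward_hidden(params, X))
    return float(np.mean((p >= 0.5) == (np.asarray(y) >= 0.5)))


def train(scaled_train: np.ndarray, labels_train: np.ndarray,
          scaled_val: Optional[np.ndarray] = None,
          labels_val: Optional[np.ndarray] = None,
          config: TrainingConfig = TrainingConfig(),
          track_every: int = 10) -> Tuple[NetworkParams, pd.DataFrame]:
    """Two-phase training; returns final parameters and history.

    Phase 1 (``epochs_init``) minimizes BCE + sparsity; phase 2
    (``epochs_joint``) adds the clustering term at the fine-tuning rate
    ``learning_rate * joint_lr_factor`` with the proximal preconditioner
    frozen, and the k-means state over the full training hidden
    representation is refreshed every ``cluster_update_interval`` epochs.
    Trailing mini-batches smaller than an eighth of ``batch_size`` are
    folded into the next epoch's reshuffle rather than stepped on.  History
    rows (every ``track_every`` epochs plus the last of each phase) record
    loss components and train/validation accuracy.  Deterministic given the
    config seed.
    """
    config.validate()
    X = np.asarray(scaled_train, dtype=float)
    y = np.asarray(labels_train, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    params = init_network(X.shape[1], config.n_hidden, 1, seed=config.seed)
    opt = _ProxAdam([p.shape for p in (params.W1, params.B1, params.W2,
                                       params.B2)],
                    lr=config.learning_rate, lambda_=config.lambda_)
    history: List[dict] = []
    clusters: Optional[ClusterState] = None
    min_batch = max(2, config.batch_size // 8)

    def run_phase(n_epochs: int, phase: str, use_clusters: bool) -> None:
        nonlocal clusters
        lr = config.learning_rate
        if use_clusters:
            lr *= config.joint_lr_factor
            opt.freeze_preconditioner()
        for epoch in range(n_epochs):
            if use_clusters and config.alpha > 0 and \
                    (epoch % config.cluster_update_interval == 0):
                h_full = forward_hidden(params, X)
                clusters = update_clusters(h_full, config.K,
                                           seed=config.seed + epoch)
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], config.batch_size):
                idx = order[start:start + config.batch_size]
                if len(idx) < min_batch and start > 0:
                    continue
                cent = clusters.centroids if (use_clusters and clusters) else None
                assign = clusters.assignments[idx] if (use_clusters and clusters) else None
                grads = _gradients(params, X[idx], y[idx], cent, assign,
                                   config.alpha if use_clusters else 0.0)
                opt.step([params.W1, params.B1, params.W2, params.B2], grads,
                         lr=lr)
            if epoch % track_every == 0 or epoch == n_epochs - 1:
                comps = compute_loss(params, X, y,
                                     clusters if use_clusters else None,
                                     config.alpha if use_clusters else 0.0,
                                     config.lambda_)
                if not np.isfinite(comps["total"]):
                    raise FloatingPointError(
                        f"non-finite loss at {phase} epoch {epoch}: {comps}")
                row = {"phase": phase, "epoch": epoch, **comps,
                       "train_accuracy": _accuracy(params, X, y)}
                if scaled_val is not None and labels_val is not None:
                    row["val_accuracy"] = _accuracy(
                        params, np.asarray(scaled_val), labels_val)
                    row["val_bce"] = compute_loss(
                        params, np.asarray(scaled_val),
                        np.asarray(labels_val, dtype=float), None, 0.0,
                        0.0)["bce"]
                history.append(row)

    run_phase(config.epochs_init, "init", use_clusters=False)
    run_phase(config.epochs_joint, "joint", use_clusters=config.alpha > 0)
    return params, pd.DataFrame(history)


def cross_validate(scaled: np.ndarray, labels: np.ndarray,
                   grid: Sequence[Tuple[int, float, float]],
                   config: TrainingConfig = TrainingConfig(),
                   folds: int = 5) -> Tuple[Tuple[int, float, float],
                                            pd.DataFrame]:
    """Stratified k-fold selection of (K, alpha, lambda).

    Picks the grid cell with the highest mean fold validation accuracy;
    ties break toward larger lambda, then smaller K (prefer sparser and
    simpler models).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(scaled, dtype=float)
    y = np.asarray(labels, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=config.seed)
    splits = list(skf.split(X, y))
    rows = []
    for K, alpha, lambda_ in grid:
        accs = []
        for train_idx, val_idx in splits:
            if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
                raise ValueError("a fold contains a single class")
            cfg = dataclasses.replace(config, K=K, alpha=alpha,
                                      lambda_=lambda_)
            params, _ = train(X[train_idx], y[train_idx], config=cfg,
                              track_every=max(1, cfg.epochs_init))
            accs.append(_accuracy(params, X[val_idx], y[val_idx]))
        rows.append({"K": K, "alpha": alpha, "lambda": lambda_,
                     "mean_val_accuracy": float(np.mean(accs)),
                     "fold_accuracies": accs})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        by=["mean_val_accuracy", "lambda", "K"],
        ascending=[False, False, True], kind="stable").iloc[0]
    return (int(best["K"]), float(best["alpha"]), float(best["lambda"])), table


def gene_weight_rss(W1: np.ndarray, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Per-gene first-layer importance: row RSS, normalized to the max.

    Returns a DataFrame indexed by gene with columns ``rss`` and ``weight``
    (= rss / max rss, in [0, 1]).
    """
    rss = np.sqrt((np.asarray(W1) ** 2).sum(axis=1))
    max_rss = rss.max() if rss.size else 0.0
    if max_rss == 0.0:
        warnings.warn("all first-layer rows are zero; weights are all 0")
        weight = np.zeros_like(rss)
    else:
        weight = rss / max_rss
    return pd.DataFrame({"rss": rss, "weight": weight},
                        index=list(gene_ids))
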