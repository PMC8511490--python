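"""Multi-kernel fusion of connectivity and node-importance features.

Each subject contributes two feature modalities extracted from their unified
network: the strict upper triangle of the symmetrized weight matrix (the
connectivity profile, length N(N-1)/2) and the vector of node-importance
scores (length N).  Per modality, a linear kernel is computed after
per-feature z-scoring fit on training subjects only; the two Gram matrices
are mixed as ``K = c1 K1 + c2 K2`` with nonnegative weights summing to one,
and a precomputed-kernel SVM classifies subjects on the mixed kernel.

Evaluation follows a repeated, stratified five-fold cross-validation: within
each outer training fold, the mixing weight and the SVM cost are selected by
an inner cross-validated grid search (weights on a 0.1-step grid, costs on a
log grid), so held-out subjects never influence standardization, weight
selection, or training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError
from .importance import NodeScores
from .network import UnifiedNetwork

__all__ = [
    "FeatureSet",
    "KernelBundle",
    "CVConfig",
    "CVResult",
    "extract_features",
    "linear_kernel",
    "mix_kernels",
    "grid_search_weights",
    "evaluate_cv",
]

DEFAULT_SVM_COSTS = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class FeatureSet:
    """Per-subject feature rows: ``connectivity`` is n_subjects x N(N-1)/2,
    ``node`` is n_subjects x N, aligned with ``labels``."""

    connectivity: np.ndarray
    node: np.ndarray
    labels: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.connectivity.shape[0]

    def modalities(self) -> list[np.ndarray]:
        return [self.connectivity, self.node]


@dataclass
class KernelBundle:
    """Per-modality Gram matrices plus mixing weights summing to one."""

    kernels: list[np.ndarray]
    weights: np.ndarray


@dataclass(frozen=True)
class CVConfig:
    """Protocol knobs for the repeated stratified five-fold evaluation."""

    n_folds: int = 5
    n_repeats: int = 5
    grid_step: float = 0.1
    svm_costs: tuple[float, ...] = DEFAULT_SVM_COSTS
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1 or self.inner_folds < 2:
            raise ValidationError("need n_folds >= 2, inner_folds >= 2, n_repeats >= 1")
        if not (0 < self.grid_step <= 1):
            raise ValidationError("grid_step must be in (0, 1]")

    def weight_grid(self) -> np.ndarray:
        """Candidate connectivity weights c1 in {0, step, ..., 1}."""
        n = int(round(1.0 / self.grid_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 12)


@dataclass
class CVResult:
    """Per-fold accuracies with the selections made on each training fold."""

    accuracies: np.ndarray  # shape (n_repeats, n_folds)
    weights: np.ndarray  # selected c1 per repeat x fold
    costs: np.ndarray  # selected SVM cost per repeat x fold

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1))


def extract_features(
    networks: Sequence[UnifiedNetwork | np.ndarray],
    scores: Sequence[NodeScores | np.ndarray],
    labels: Sequence[str],
) -> FeatureSet:
    """Vectorize each subject's network and node scores.

    Connectivity is the strict upper triangle (row-major) of the symmetrized
    ``(W + W^T)/2`` with the diagonal zeroed; node features are the score
    vectors as-is.
    """
    if not (len(networks) == len(scores) == len(labels)):
        raise ValidationError("networks, scores and labels must align")
    ws = [net.W if isinstance(net, UnifiedNetwork) else np.asarray(net) for net in networks]
    ns = {w.shape[0] for w in ws}
    if len(ns) != 1:
        raise ValidationError(f"inconsistent region counts across subjects: {sorted(ns)}")
    n = ns.pop()
    iu = np.triu_indices(n, k=1)
    conn = np.empty((len(ws), n * (n - 1) // 2))
    for i, w in enumerate(ws):
        sym = (w + w.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        conn[i] = sym[iu]
    node = np.vstack(
        [sc.s if isinstance(sc, NodeScores) else np.asarray(sc) for sc in scores]
    )
    if node.shape[1] != n:
        raise ValidationError("node score length does not match region count")
    return FeatureSet(connectivity=conn, node=node, labels=np.asarray(labels))


def _fit_scaler(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant features pass through centred
    return mean, std


def linear_kernel(
    features: np.ndarray,
    test_features: np.ndarray | None = None,
    *,
    standardize: bool = True,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Linear Gram matrix, optionally after z-scoring fit on ``features``.

    With ``test_features`` given, returns ``(K_train, K_test_train)`` where
    the test rows are standardized with the training statistics — the
    leak-free way to kernelize held-out subjects.
    """
    features = np.asarray(features, dtype=float)
    if not np.isfinite(features).all():
        raise ValidationError("features must be finite")
    if standardize:
        mean, std = _fit_scaler(features)
        z = (features - mean) / std
    else:
        z = features
    k_train = z @ z.T
    if test_features is None:
        return k_train
    test = np.asarray(test_features, dtype=float)
    zt = (test - mean) / std if standardize else test
    return k_train, zt @ z.T


def mix_kernels(bundle: KernelBundle) -> np.ndarray:
    """Convex combination ``sum_m c_m K_m`` of the per-modality kernels."""
    w = np.asarray(bundle.weights, dtype=float)
    if len(bundle.kernels) != w.size:
        raise ValidationError("one weight per kernel required")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must be nonnegative and sum to 1")
    out = np.zeros_like(bundle.kernels[0], dtype=float)
    for c, k in zip(w, bundle.kernels):
        out = out + c * k
    return out


def _mixed_grams(
    modalities: list[np.ndarray],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    c1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and test-vs-training mixed Grams with train-fitted scaling."""
    weights = np.array([c1, 1.0 - c1])
    k_tr = []
    k_te = []
    for feats in modalities:
        ktr, kte = linear_kernel(feats[train_idx], feats[test_idx])
        k_tr.append(ktr)
        k_te.append(kte)
    return (
        mix_kernels(KernelBundle(k_tr, weights)),
        sum(c * k for c, k in zip(weights, k_te)),
    )


def _accuracy(
    modalities: list[np.ndarray],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    c1: float,
    cost: float,
) -> float:
    k_train, k_test = _mixed_grams(modalities, train_idx, test_idx, c1)
    clf = SVC(C=cost, kernel="precomputed")
    clf.fit(k_train, y[train_idx])
    return float((clf.predict(k_test) == y[test_idx]).mean())


def grid_search_weights(
    modalities: list[np.ndarray],
    labels: np.ndarray,
    config: CVConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Select the kernel mix and SVM cost by inner cross-validation.

    Evaluates every (c1, cost) candidate by ``config.inner_folds``-fold
    stratified CV on the given (training) subjects and returns the mixing
    weights ``(c1, 1 - c1)`` and cost with the best mean inner accuracy.
    Ties break toward the larger connectivity weight, then the smaller cost.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("grid search needs at least two classes")
    rng_seed = config.seed if seed is None else seed
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=rng_seed
    )
    splits = list(skf.split(np.zeros(len(labels)), labels))

    best = None
    # iteration order realizes the tie-break: larger c1 first, smaller cost first
    for c1 in sorted(config.weight_grid(), reverse=True):
        for cost in sorted(config.svm_costs):
            acc = np.mean(
                [
                    _accuracy(modalities, labels, tr, te, c1, cost)
                    for tr, te in splits
                ]
            )
            if best is None or acc > best[0]:
                best = (acc, c1, cost)
    _, c1, cost = best
    return np.array([c1, 1.0 - c1]), cost


def evaluate_cv(features: FeatureSet, config: CVConfig = CVConfig()) -> CVResult:
    """Repeated stratified five-fold cross-validation with nested selection.

    For each repeat a fresh stratified split is drawn; within each outer
    training fold the kernel weights and SVM cost are chosen by
    ``grid_search_weights``, the SVM is trained on the mixed training kernel,
    and the held-out subjects are scored.  Test subjects never enter
    standardization statistics, weight selection, or training.
    """
    labels = features.labels
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("evaluation needs at least two classes")
    if counts.min() < config.n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} subjects; need >= {config.n_folds} "
            "for stratified folds"
        )
    modalities = features.modalities()
    accs = np.zeros((config.n_repeats, config.n_folds))
    sel_w = np.zeros_like(accs)
    sel_c = np.zeros_like(accs)
    for rep in range(config.n_repeats):
        rep_seed = config.seed + rep
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=rep_seed
        )
        for fold, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(len(labels)), labels)
        ):
            weights, cost = grid_search_weights(
                [m[train_idx] for m in modalities],
                labels[train_idx],
                config,
                seed=rep_seed,
            )
            k_train, k_test = _mixed_grams(modalities, train_idx, test_idx, weights[0])
            clf = SVC(C=cost, kernel="precomputed")
            clf.fit(k_train, labels[train_idx])
            accs[rep, fold] = float(
                (clf.predict(k_test) == labels[test_idx]).mean()
            )
            sel_w[rep, fold] = weights[0]
            sel_c[rep, fold] = cost
    return CVResult(accuracies=accs, weights=sel_w, costs=sel_c)
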