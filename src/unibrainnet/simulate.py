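"""Synthetic multimodal cohorts with planted network structure.

Real inputs to the pipeline are, per subject, a matrix of regional BOLD-like
time series (K time points x N regions) and a symmetric nonnegative matrix of
DTI fiber counts between the same N regions.  No such cohort can be shipped
with the package, so this module fabricates subjects whose ground truth is
known: each subject carries a planted self-representation matrix ``W_true``
(every region's signal is an exact linear combination of a few other regions
in its community), and fiber counts concentrated on within-community pairs.
Downstream stages — network estimation, node scoring, classification — can
then be tested against the planted structure.

The generator emulates community structure and low-rank regional dependence,
not BOLD hemodynamics or tractography physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "PlantedModel",
    "SubjectSample",
    "simulate_subject",
    "simulate_cohort",
    "planted_weights",
    "planted_support",
    "contiguous_blocks",
    "make_toy_graph",
]


def contiguous_blocks(n_regions: int, n_blocks: int) -> tuple[tuple[int, ...], ...]:
    """Partition ``range(n_regions)`` into ``n_blocks`` near-equal contiguous runs."""
    if n_blocks < 1 or n_blocks > n_regions:
        raise ValidationError(f"n_blocks must be in [1, {n_regions}], got {n_blocks}")
    splits = np.array_split(np.arange(n_regions), n_blocks)
    return tuple(tuple(int(i) for i in s) for s in splits)


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth description of one class of synthetic subjects.

    Parameters
    ----------
    n_regions
        Number of network nodes N (brain regions).
    n_timepoints
        Number of time points K per regional series.
    rank
        Total factor dimension of the planted signals; controls the rank of
        the community sub-blocks of ``W_true``.  Split across blocks in
        proportion to block size.
    blocks
        Partition of ``range(n_regions)`` into communities.  Every block must
        have at least three members so that exact self-representation with a
        zero diagonal and unit column sums is feasible.
    noise_sd
        Standard deviation of i.i.d. Gaussian noise added to the time series.
    fiber_scale
        Mean fiber count on within-block region pairs; between-block pairs
        have mean 1.
    seed
        Seed fixing the class-level structure (factors, loadings, W_true).
    """

    n_regions: int
    n_timepoints: int
    rank: int = 6
    blocks: tuple[tuple[int, ...], ...] | None = None
    noise_sd: float = 0.1
    fiber_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_timepoints < 2:
            raise ValidationError(
                "invalid model: need n_regions >= 2 and n_timepoints >= 2, got "
                f"n_regions={self.n_regions}, n_timepoints={self.n_timepoints}"
            )
        if self.blocks is None:
            object.__setattr__(self, "blocks", contiguous_blocks(self.n_regions, 2))
        flat = sorted(i for b in self.blocks for i in b)
        if flat != list(range(self.n_regions)):
            raise ValidationError("blocks must partition the region index set exactly")
        if any(len(b) < 3 for b in self.blocks):
            raise ValidationError("every block needs at least 3 regions")
        if not (1 <= self.rank <= self.n_regions):
            raise ValidationError(f"rank must be in [1, n_regions], got {self.rank}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.fiber_scale <= 0:
            raise ValidationError("fiber_scale must be positive")

    def block_ranks(self) -> list[int]:
        """Factor dimension allotted to each block (>=1, <= block size - 2)."""
        out = []
        for b in self.blocks:
            r = int(round(self.rank * len(b) / self.n_regions))
            out.append(int(np.clip(r, 1, len(b) - 2)))
        return out


@dataclass
class SubjectSample:
    """One synthetic subject: time series ``X`` (K x N), fiber counts ``G``
    (N x N, symmetric, nonnegative integers, zero diagonal) and a class label."""

    X: np.ndarray
    G: np.ndarray
    label: str

    def validate(self) -> None:
        if not np.allclose(self.G, self.G.T):
            raise ValidationError("fiber matrix must be symmetric")
        if (self.G < 0).any():
            raise ValidationError("fiber matrix must be nonnegative")
        if np.diag(self.G).any():
            raise ValidationError("fiber matrix must have a zero diagonal")
        if (self.X.std(axis=0) == 0).any():
            raise ValidationError("time series has a constant column")


def _class_structure(model: PlantedModel) -> tuple[np.ndarray, np.ndarray]:
    """Build the class-level base signal ``X0`` and planted matrix ``W_true``.

    Within each block, regional signals are a rank-limited factor model
    ``X0[:, block] = F @ A`` with K x r factors F and r x n_b loadings A.
    ``W_true`` is then the block-wise combination-weight matrix solving
    ``X0 = X0 @ W_true`` exactly with a zero diagonal and unit column sums:
    for each region j, its loading vector is expressed through the other
    loadings of its block under the constraint that the weights sum to one
    (minimum-norm solution of the stacked linear system).
    """
    rng = np.random.default_rng(model.seed)
    n, k = model.n_regions, model.n_timepoints
    x0 = np.zeros((k, n))
    w_true = np.zeros((n, n))
    for block, r in zip(model.blocks, model.block_ranks()):
        idx = np.asarray(block)
        factors = rng.standard_normal((k, r))
        loadings = rng.standard_normal((r, len(idx)))
        x0[:, idx] = factors @ loadings
        for pos, j in enumerate(idx):
            others = np.delete(np.arange(len(idx)), pos)
            # A_{-j} w = a_j  together with  1^T w = 1
            lhs = np.vstack([loadings[:, others], np.ones((1, len(others)))])
            rhs = np.concatenate([loadings[:, pos], [1.0]])
            w, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
            resid = np.abs(lhs @ w - rhs).max()
            if resid > 1e-8:  # pragma: no cover - generic inputs are feasible
                raise ValidationError(
                    f"planted representation infeasible for region {j} "
                    f"(residual {resid:.2e}); use larger blocks or smaller rank"
                )
            w_true[idx[others], j] = w
    return x0, w_true


def planted_weights(model: PlantedModel) -> np.ndarray:
    """The planted self-representation matrix ``W_true`` (zero diagonal,
    columns sum to one, support confined to within-block pairs)."""
    return _class_structure(model)[1]


def planted_support(model: PlantedModel) -> np.ndarray:
    """Boolean N x N mask of within-block off-diagonal pairs (planted edges)."""
    n = model.n_regions
    mask = np.zeros((n, n), dtype=bool)
    for block in model.blocks:
        idx = np.asarray(block)
        mask[np.ix_(idx, idx)] = True
    np.fill_diagonal(mask, False)
    return mask


def simulate_subject(
    model: PlantedModel,
    seed: int,
    *,
    w_jitter: float = 0.0,
    label: str = "class_0",
) -> SubjectSample:
    """Draw one subject from a planted model.

    The subject's series are ``X = X0 @ W_subj + E`` where ``W_subj`` is the
    class matrix ``W_true`` with entries multiplied by ``(1 + delta)``,
    ``delta ~ U(-w_jitter, w_jitter)`` (within-class variability), and ``E``
    is i.i.d. Gaussian noise with sd ``model.noise_sd``.  With zero jitter and
    zero noise, ``X`` satisfies ``X = X @ W_true`` exactly.  Fiber counts are
    Poisson with mean ``fiber_scale`` on within-block pairs and mean 1
    elsewhere, symmetrized by averaging and rounding.  Identical seeds give
    bit-identical output.
    """
    x0, w_true = _class_structure(model)
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, int(seed)]))
    n = model.n_regions

    w_subj = w_true
    if w_jitter > 0:
        delta = rng.uniform(-w_jitter, w_jitter, size=(n, n))
        w_subj = w_true * (1.0 + delta)
        np.fill_diagonal(w_subj, 0.0)

    x = x0 @ w_subj
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=x.shape)

    lam = np.ones((n, n))
    lam[planted_support(model)] = model.fiber_scale
    counts = rng.poisson(lam).astype(float)
    g = np.rint((counts + counts.T) / 2.0)
    np.fill_diagonal(g, 0.0)

    sample = SubjectSample(X=x, G=g, label=label)
    sample.validate()
    return sample


def simulate_cohort(
    models_by_class: Sequence[PlantedModel],
    n_per_class: int,
    seed: int,
    *,
    labels: Sequence[str] | None = None,
    w_jitter: float = 0.1,
) -> list[SubjectSample]:
    """Draw ``n_per_class`` subjects from each class model.

    Subjects within a class share the class's planted structure but get fresh
    noise and a fresh multiplicative jitter of ``W_true``, so they are similar
    without being identical.  Reproducible under ``seed``.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if labels is None:
        labels = [f"class_{k}" for k in range(len(models_by_class))]
    if len(labels) != len(models_by_class):
        raise ValidationError("labels must match models_by_class in length")
    cohort: list[SubjectSample] = []
    for k, (model, label) in enumerate(zip(models_by_class, labels)):
        for i in range(n_per_class):
            child = int(
                np.random.SeedSequence([int(seed), k, i]).generate_state(1)[0] % (2**31)
            )
            cohort.append(
                simulate_subject(model, child, w_jitter=w_jitter, label=label)
            )
    return cohort


def make_toy_graph(n_nodes: int, edge_list: Sequence[tuple[int, int]]) -> np.ndarray:
    """Binary adjacency matrix from an explicit edge list (0-based, directed:
    entry ``B[u, v] = 1`` means an edge from u to v).  Self-loops and
    out-of-range indices are rejected."""
    b = np.zeros((n_nodes, n_nodes), dtype=float)
    for u, v in edge_list:
        if not (0 <= u < n_nodes and 0 <= v < n_nodes):
            raise ValidationError(f"edge ({u}, {v}) out of range for {n_nodes} nodes")
        if u == v:
            raise ValidationError(f"self-loop ({u}, {v}) not allowed")
        b[u, v] = 1.0
    return b
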