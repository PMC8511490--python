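"""Unified brain-network estimation by ADMM.

A subject's network is the N x N weight matrix ``W`` minimising

    || X~ - X~ W ||_F^2 + alpha ||W||_* + beta tr(W L W^T) + gamma ||U||_F^2
    subject to  X~ = U X,   L = D - G,

where ``X`` is the (column-standardised) K x N regional time-series matrix,
``U`` an M x K projection learned jointly with the network (space alignment),
``G`` the symmetric DTI fiber-count matrix with graph Laplacian ``L``, and
``||.||_*`` the nuclear norm promoting low rank.  The self-representation
term asks every region's (aligned) signal to be reproduced from the other
regions' signals; the Laplacian term pulls the weight profiles of strongly
fiber-connected regions together; the nuclear norm encodes that only a few
latent region combinations drive the whole network.

The problem is split with auxiliaries ``P = W`` (nuclear norm) and ``Q = W``
(Laplacian) and solved by an alternating-direction method of multipliers on
the augmented Lagrangian: each block update below is the exact minimiser of
its subproblem, multipliers ascend on the constraint residuals, and the
penalty ``mu`` grows geometrically up to a cap.  A plain Pearson-correlation
network is provided as the classical single-modality baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SolverDivergenceError, ValidationError

__all__ = [
    "HyperParams",
    "AdmmState",
    "StructuralLaplacian",
    "UnifiedNetwork",
    "build_laplacian",
    "pearson_network",
    "soft_threshold_svd",
    "update_w",
    "update_p",
    "update_q",
    "update_u",
    "update_xtilde",
    "update_multipliers",
    "objective_value",
    "lagrangian_value",
    "standardize_columns",
    "construct_unified_network",
]


@dataclass(frozen=True)
class HyperParams:
    """Solver hyperparameters.

    alpha, beta, gamma weight the nuclear-norm, Laplacian and projection
    terms; ``m`` is the aligned dimension M (``None`` means M = K, i.e. no
    dimension reduction); ``mu0``, ``rho``, ``mu_max`` drive the penalty
    schedule ``mu <- min(rho * mu, mu_max)``; ``eps`` is the infinity-norm
    residual tolerance.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    m: int | None = None
    mu0: float = 0.1
    rho: float = 1.01
    mu_max: float = 1e7
    eps: float = 1e-7
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValidationError("alpha, beta, gamma must be nonnegative")
        if self.rho <= 1:
            raise ValidationError("rho must be > 1")
        if self.eps <= 0 or self.mu0 <= 0 or self.mu_max <= 0:
            raise ValidationError("eps, mu0, mu_max must be positive")
        if self.mu0 > self.mu_max:
            raise ValidationError("mu0 must not exceed mu_max")
        if self.m is not None and self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class StructuralLaplacian:
    """Graph Laplacian ``L = D - G`` of the fiber-count matrix."""

    G: np.ndarray
    D: np.ndarray
    L: np.ndarray


@dataclass
class AdmmState:
    """All iterates of the augmented-Lagrangian solver.

    ``K_gram`` caches the Gram matrix ``X~^T X~`` of the current aligned data
    (the matrix called K in the W update).
    """

    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    Xt: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray
    Y3: np.ndarray
    mu: float
    K_gram: np.ndarray


@dataclass
class UnifiedNetwork:
    """Solver output: the network ``W`` plus convergence diagnostics."""

    W: np.ndarray
    converged: bool
    n_iter: int
    residual_history: list[tuple[float, float, float]] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    lagrangian_history: list[float] = field(default_factory=list)


def build_laplacian(G: np.ndarray, *, atol: float = 1e-8) -> StructuralLaplacian:
    """Degree matrix and Laplacian ``L = D - G`` of a nonnegative symmetric G.

    G is symmetrized by averaging when its asymmetry is below ``atol``;
    materially asymmetric or negative input is rejected.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValidationError(f"G must be square, got shape {G.shape}")
    if (G < 0).any():
        raise ValidationError("G must be elementwise nonnegative")
    if np.abs(G - G.T).max() > atol:
        raise ValidationError("G is materially asymmetric")
    G = (G + G.T) / 2.0
    D = np.diag(G.sum(axis=1))
    return StructuralLaplacian(G=G, D=D, L=D - G)


def pearson_network(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between regional time series (columns of
    X); the classical functional-connectivity baseline."""
    X = np.asarray(X, dtype=float)
    stds = X.std(axis=0)
    dead = np.flatnonzero(stds == 0)
    if dead.size:
        raise ValidationError(f"zero-variance region(s): {dead.tolist()}")
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return C


def soft_threshold_svd(M: np.ndarray, lam: float) -> np.ndarray:
    """Singular-value thresholding: the proximal operator of ``lam ||.||_*``.

    Returns ``U S_lam(Sigma) V^T`` where each singular value is shrunk toward
    zero by ``lam`` and floored at zero; this is the unique minimiser of
    ``lam ||P||_* + 1/2 ||P - M||_F^2``.
    """
    if lam < 0:
        raise ValidationError("threshold must be nonnegative")
    if lam == 0:
        return np.asarray(M, dtype=float).copy()
    u, s, vt = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    return (u * np.maximum(s - lam, 0.0)) @ vt


def update_w(state: AdmmState) -> np.ndarray:
    """Exact minimiser of the W block: with K = X~^T X~,
    W = (K + K^T + 2 mu I)^{-1} (K + K^T + mu (P + Q) + Y1 + Y2)."""
    K = state.K_gram
    n = K.shape[0]
    ks = K + K.T
    lhs = ks + 2.0 * state.mu * np.eye(n)
    rhs = ks + state.mu * (state.P + state.Q) + state.Y1 + state.Y2
    return np.linalg.solve(lhs, rhs)


def update_p(state: AdmmState, alpha: float) -> np.ndarray:
    """Exact minimiser of the P block: SVT of ``W - Y1/mu`` at ``alpha/mu``."""
    return soft_threshold_svd(state.W - state.Y1 / state.mu, alpha / state.mu)


def update_q(state: AdmmState, beta: float, lap: StructuralLaplacian) -> np.ndarray:
    """Exact minimiser of the Q block:
    Q = (mu W - Y2) (beta (L + L^T) + mu I)^{-1}."""
    n = state.W.shape[0]
    lhs = beta * (lap.L + lap.L.T) + state.mu * np.eye(n)
    rhs = state.mu * state.W - state.Y2
    # right inverse of a symmetric matrix
    return np.linalg.solve(lhs, rhs.T).T


def update_u(
    state: AdmmState,
    gamma: float,
    X: np.ndarray,
    XXt: np.ndarray | None = None,
) -> np.ndarray:
    """Exact minimiser of the U block:
    U = (mu X~ X^T + Y3 X^T) (2 gamma I + mu X X^T)^{-1}."""
    if XXt is None:
        XXt = X @ X.T
    k = X.shape[0]
    lhs = 2.0 * gamma * np.eye(k) + state.mu * XXt
    rhs = (state.mu * state.Xt + state.Y3) @ X.T
    try:
        return np.linalg.solve(lhs, rhs.T).T
    except np.linalg.LinAlgError as exc:  # gamma = 0 with rank-deficient X
        raise ValidationError(
            "U update is singular; use gamma > 0 when X X^T is rank-deficient"
        ) from exc


def update_xtilde(state: AdmmState, X: np.ndarray) -> np.ndarray:
    """Exact minimiser of the X~ block:
    X~ = (mu U X - Y3) (2 I - 2 W - 2 W^T + 2 W W^T + mu I)^{-1}.
    The bracket equals ``2 (I - W)(I - W)^T + mu I`` and is SPD."""
    n = state.W.shape[0]
    W = state.W
    lhs = 2.0 * np.eye(n) - 2.0 * W - 2.0 * W.T + 2.0 * W @ W.T + state.mu * np.eye(n)
    rhs = state.mu * state.U @ X - state.Y3
    return np.linalg.solve(lhs, rhs.T).T


def update_multipliers(state: AdmmState, params: HyperParams, X: np.ndarray) -> AdmmState:
    """Multiplier ascent and penalty growth:
    Y1 += mu (P - W); Y2 += mu (Q - W); Y3 += mu (X~ - U X);
    mu <- min(rho mu, mu_max).  Mutates and returns ``state``."""
    state.Y1 = state.Y1 + state.mu * (state.P - state.W)
    state.Y2 = state.Y2 + state.mu * (state.Q - state.W)
    state.Y3 = state.Y3 + state.mu * (state.Xt - state.U @ X)
    state.mu = min(params.rho * state.mu, params.mu_max)
    return state


def _nuclear_norm(M: np.ndarray) -> float:
    return float(np.linalg.svd(M, compute_uv=False).sum())


def objective_value(
    W: np.ndarray,
    U: np.ndarray,
    X: np.ndarray,
    lap: StructuralLaplacian,
    params: HyperParams,
) -> float:
    """Constrained objective with ``X~`` substituted by ``U X``:
    ||UX - UXW||_F^2 + alpha ||W||_* + beta tr(W L W^T) + gamma ||U||_F^2."""
    xt = U @ X
    fit = float(np.linalg.norm(xt - xt @ W, "fro") ** 2)
    return (
        fit
        + params.alpha * _nuclear_norm(W)
        + params.beta * float(np.trace(W @ lap.L @ W.T))
        + params.gamma * float(np.linalg.norm(U, "fro") ** 2)
    )


def lagrangian_value(
    state: AdmmState,
    X: np.ndarray,
    lap: StructuralLaplacian,
    params: HyperParams,
) -> float:
    """Value of the augmented Lagrangian at the current iterates."""
    r1 = state.P - state.W
    r2 = state.Q - state.W
    r3 = state.Xt - state.U @ X
    fit = float(np.linalg.norm(state.Xt - state.Xt @ state.W, "fro") ** 2)
    val = (
        fit
        + params.alpha * _nuclear_norm(state.P)
        + params.beta * float(np.trace(state.Q @ lap.L @ state.Q.T))
        + params.gamma * float(np.linalg.norm(state.U, "fro") ** 2)
        + float(np.sum(state.Y1 * r1) + np.sum(state.Y2 * r2) + np.sum(state.Y3 * r3))
        + state.mu
        / 2.0
        * float(
            np.linalg.norm(r1, "fro") ** 2
            + np.linalg.norm(r2, "fro") ** 2
            + np.linalg.norm(r3, "fro") ** 2
        )
    )
    return val


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each region's series (zero mean, unit variance per column)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        raise ValidationError(f"zero-variance region(s): {dead.tolist()}")
    return (X - mean) / std


def _check_finite(M: np.ndarray, name: str, iteration: int) -> None:
    if not np.isfinite(M).all():
        raise SolverDivergenceError(
            f"non-finite values in iterate {name!r} at iteration {iteration}"
        )


def construct_unified_network(
    X: np.ndarray,
    G: np.ndarray | None,
    params: HyperParams = HyperParams(),
    *,
    standardize: bool = True,
    align: bool = True,
    keep_history: bool = True,
) -> UnifiedNetwork:
    """Estimate the unified network ``W`` for one subject.

    Parameters
    ----------
    X
        K x N time-series matrix (rows are time points, columns regions).
    G
        N x N symmetric nonnegative fiber-count matrix, or ``None`` to drop
        the structural term (equivalent to beta = 0).
    params
        Solver hyperparameters; ``params.m`` is the aligned dimension.
    standardize
        Column z-score X before solving (default).  The self-representation
        and the Pearson baseline then live on comparable scales.
    align
        If False, skip space alignment entirely: the projection U is pinned
        to the identity and ``X~ = X`` throughout (the "work in the original
        feature space" ablation), and the alignment residual is identically
        zero.
    keep_history
        Record residuals, objective and Lagrangian values each iteration.

    The blocks are visited in the fixed order W, P, Q, U, X~, multipliers,
    starting from W = P = Q = 0, U a first-M-rows selector, X~ = U X and zero
    multipliers, and iterate until the three constraint residuals
    ``||P - W||_inf, ||Q - W||_inf, ||X~ - U X||_inf`` all fall below
    ``params.eps`` or ``max_iter`` is reached.  Fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D (timepoints x regions) matrix")
    k, n = X.shape
    if standardize:
        X = standardize_columns(X)

    lap = build_laplacian(G if G is not None else np.zeros((n, n)))
    if lap.L.shape[0] != n:
        raise ValidationError(
            f"G is {lap.L.shape[0]}x{lap.L.shape[0]} but X has {n} regions"
        )

    m = k if (params.m is None or not align) else int(params.m)
    if m > k:
        raise ValidationError(f"aligned dimension m={m} exceeds K={k}")

    u0 = np.eye(m, k)
    state = AdmmState(
        W=np.zeros((n, n)),
        P=np.zeros((n, n)),
        Q=np.zeros((n, n)),
        U=u0,
        Xt=u0 @ X,
        Y1=np.zeros((n, n)),
        Y2=np.zeros((n, n)),
        Y3=np.zeros((m, n)),
        mu=params.mu0,
        K_gram=(u0 @ X).T @ (u0 @ X),
    )
    XXt = X @ X.T if align else None

    result = UnifiedNetwork(W=state.W, converged=False, n_iter=0)
    for it in range(1, params.max_iter + 1):
        state.K_gram = state.Xt.T @ state.Xt
        state.W = update_w(state)
        state.P = update_p(state, params.alpha)
        state.Q = update_q(state, params.beta, lap)
        if align:
            state.U = update_u(state, params.gamma, X, XXt)
            state.Xt = update_xtilde(state, X)
        for name, mat in (("W", state.W), ("P", state.P), ("Q", state.Q),
                          ("U", state.U), ("Xt", state.Xt)):
            _check_finite(mat, name, it)

        ux = state.U @ X
        res = (
            float(np.abs(state.P - state.W).max()),
            float(np.abs(state.Q - state.W).max()),
            float(np.abs(state.Xt - ux).max()) if align else 0.0,
        )
        if keep_history:
            result.residual_history.append(res)
            result.objective_history.append(
                objective_value(state.W, state.U, X, lap, params)
            )
            result.lagrangian_history.append(
                lagrangian_value(state, X, lap, params)
            )
        result.n_iter = it
        if max(res) < params.eps:
            result.converged = True
            break
        update_multipliers(state, params, X)

    result.W = state.W
    return result
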