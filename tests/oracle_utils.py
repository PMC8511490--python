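"""Independent numerical oracles used by the tests.

Each oracle minimizes the relevant (sub)problem with a generic optimizer and
gradients assembled directly from the objective's terms, never reusing the
closed forms under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

LBFGS_OPTS = dict(maxiter=50_000, ftol=1e-18, gtol=1e-13)


def minimize_smooth(fun_grad, x0: np.ndarray) -> np.ndarray:
    """High-precision L-BFGS on a smooth function returning (value, grad)."""
    res = minimize(fun_grad, x0.ravel(), jac=True, method="L-BFGS-B", options=LBFGS_OPTS)
    return res.x.reshape(x0.shape)


def nuclear_prox_oracle(M: np.ndarray, lam: float, seed: int = 0, n_restarts: int = 3) -> np.ndarray:
    """Brute-force minimizer of ``lam ||P||_* + 1/2 ||P - M||_F^2``.

    Uses the variational identity ``||P||_* = min_{P=AB} (||A||_F^2 +
    ||B||_F^2)/2`` so the problem becomes smooth in the factors (A, B); the
    best of a few random starts is returned.  No singular-value shrinkage is
    involved anywhere.
    """
    n, m = M.shape
    k = min(n, m)
    rng = np.random.default_rng(seed)
    best_val, best_p = np.inf, None
    for _ in range(n_restarts):
        x0 = rng.standard_normal(n * k + k * m) * 0.5

        def fun(x):
            A = x[: n * k].reshape(n, k)
            B = x[n * k:].reshape(k, m)
            R = A @ B - M
            val = 0.5 * lam * (np.sum(A * A) + np.sum(B * B)) + 0.5 * np.sum(R * R)
            gA = lam * A + R @ B.T
            gB = lam * B + A.T @ R
            return val, np.concatenate([gA.ravel(), gB.ravel()])

        res = minimize(fun, x0, jac=True, method="L-BFGS-B", options=LBFGS_OPTS)
        if res.fun < best_val:
            best_val = res.fun
            A = res.x[: n * k].reshape(n, k)
            B = res.x[n * k:].reshape(k, m)
            best_p = A @ B
    return best_p


def w_subproblem_oracle(Xt, P, Q, Y1, Y2, mu):
    """Generic minimizer of the W block of the augmented Lagrangian."""
    n = P.shape[0]
    G = Xt.T @ Xt  # assembled here only to form the fit gradient 2 X~^T X~ (W - I)

    def fun(x):
        W = x.reshape(n, n)
        R = Xt - Xt @ W
        val = (
            np.sum(R * R)
            + np.sum(Y1 * (P - W)) + np.sum(Y2 * (Q - W))
            + mu / 2 * (np.sum((P - W) ** 2) + np.sum((Q - W) ** 2))
        )
        grad = 2 * G @ (W - np.eye(n)) - Y1 - Y2 + mu * (W - P) + mu * (W - Q)
        return val, grad.ravel()

    return minimize_smooth(fun, np.zeros((n, n)))


def p_subproblem_oracle(W, Y1, mu, alpha, seed=0):
    """Generic minimizer of the P block: alpha||P||_* + <Y1, P-W> + mu/2||P-W||^2.

    Completing the square, this is the nuclear prox of ``W - Y1/mu`` at
    threshold ``alpha/mu`` — solved here with the factorization oracle.
    """
    return nuclear_prox_oracle(W - Y1 / mu, alpha / mu, seed=seed)


def q_subproblem_oracle(W, Y2, mu, beta, L):
    n = W.shape[0]
    Ls = L + L.T

    def fun(x):
        Q = x.reshape(n, n)
        val = (
            beta * np.trace(Q @ L @ Q.T)
            + np.sum(Y2 * (Q - W))
            + mu / 2 * np.sum((Q - W) ** 2)
        )
        grad = beta * Q @ Ls + Y2 + mu * (Q - W)
        return val, grad.ravel()

    return minimize_smooth(fun, np.zeros((n, n)))


def u_subproblem_oracle(Xt, Y3, mu, gamma, X):
    m, _ = Xt.shape
    k = X.shape[0]

    def fun(x):
        U = x.reshape(m, k)
        R = Xt - U @ X
        val = gamma * np.sum(U * U) + np.sum(Y3 * R) + mu / 2 * np.sum(R * R)
        grad = 2 * gamma * U - Y3 @ X.T - mu * R @ X.T
        return val, grad.ravel()

    return minimize_smooth(fun, np.zeros((m, k)))


def xtilde_subproblem_oracle(W, U, Y3, mu, X):
    m = U.shape[0]
    n = W.shape[0]
    UX = U @ X

    def fun(x):
        Xt = x.reshape(m, n)
        F = Xt - Xt @ W
        R = Xt - UX
        val = np.sum(F * F) + np.sum(Y3 * R) + mu / 2 * np.sum(R * R)
        grad = 2 * F @ (np.eye(n) - W).T + Y3 + mu * R
        return val, grad.ravel()

    return minimize_smooth(fun, np.zeros((m, n)))


def pagerank_eigen_oracle(T: np.ndarray) -> np.ndarray:
    """Dominant-eigenvalue eigenvector of the transfer matrix, normalized to
    sum 1, from a dense eigendecomposition."""
    vals, vecs = np.linalg.eig(T)
    i = int(np.argmax(vals.real))
    v = vecs[:, i].real
    v = np.abs(v)
    return v / v.sum()


def all_pairs_shortest_paths(B: np.ndarray) -> np.ndarray:
    """Brute-force BFS distances on a binary undirected adjacency matrix;
    unreachable pairs get inf."""
    n = B.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if B[u, v] and dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist
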