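"""Node importance on the thresholded network.

The estimated network ``W`` is first binarized: entries of the symmetrized
magnitude ``max(|W|, |W^T|)`` at or above a threshold ``r`` become edges.
Node importance is then scored by a simplified PageRank — the fixed point of
``s = T s`` where the transfer matrix ``T`` spreads each node's score equally
over its links, with no damping factor — or by one of four classical
topological comparators (local clustering coefficient, degree, closeness
centrality, radiality).

The simplified PageRank has no teleportation, so two conventions are needed
to make the iteration well-posed on arbitrary graphs: the score mass sitting
on dangling (link-less) nodes is redistributed uniformly every step, keeping
``sum(s) = 1``; and a lazy half-step ``s <- (s + T s)/2`` is used, which has
exactly the same fixed points as ``s = T s`` but also converges on periodic
(e.g. bipartite) graphs where the plain power iteration oscillates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import SolverDivergenceError, ValidationError

__all__ = [
    "BinaryGraph",
    "TransferMatrix",
    "NodeScores",
    "binarize",
    "transfer_matrix",
    "pagerank",
    "node_scores",
    "COMPARATOR_METHODS",
]

COMPARATOR_METHODS = ("clustering", "avgdeg", "closeness", "radiality")


@dataclass
class BinaryGraph:
    """0/1 adjacency matrix with zero diagonal; ``B[u, v] = 1`` is an edge
    from u to v (symmetric B reads as an undirected graph)."""

    B: np.ndarray
    r: float | None = None
    all_zero: bool = False

    @classmethod
    def from_matrix(cls, B: np.ndarray) -> "BinaryGraph":
        B = np.asarray(B, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.isin(B, (0.0, 1.0)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if np.diag(B).any():
            raise ValidationError("adjacency must have a zero diagonal")
        return cls(B=B, all_zero=not B.any())

    @property
    def n_nodes(self) -> int:
        return self.B.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.B.sum())


@dataclass
class TransferMatrix:
    """Column-stochastic transfer matrix: ``T[v, u] = 1/deg(u)`` if there is
    an edge u->v, else 0; ``dangling`` lists nodes with no links."""

    T: np.ndarray
    dangling: tuple[int, ...]


@dataclass
class NodeScores:
    """Per-node importance scores.  PageRank scores are nonnegative and sum
    to one; comparator scores use their standard graph-theoretic scales."""

    s: np.ndarray
    method: str
    n_iter: int | None = None


def binarize(W: np.ndarray, r: float, *, relative: bool = False) -> BinaryGraph:
    """Threshold a network into a binary undirected graph.

    The solver's W is neither symmetric nor sign-constrained, so the edge
    strength is taken as ``max(|W|, |W^T|)`` and an edge is kept where it is
    at or above ``r``; the diagonal is dropped.  ``r`` lives in [0, 1] (the
    useful range is roughly 0.1-0.8; too small gives a near-complete graph,
    too large an empty one — an all-zero result is allowed but flagged).

    With ``relative=True`` the cut is ``r`` times the largest off-diagonal
    strength, making the sparsity controlled by ``r`` independent of the
    overall scale of W (which varies with the regularization weights).
    """
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise ValidationError("W must be finite")
    if not (0.0 <= r <= 1.0):
        raise ValidationError(f"threshold r must be in [0, 1], got {r}")
    strength = np.maximum(np.abs(W), np.abs(W.T))
    np.fill_diagonal(strength, 0.0)
    cut = r * strength.max() if relative else r
    B = np.zeros_like(strength) if (relative and strength.max() == 0) else (
        strength >= cut
    ).astype(float)
    np.fill_diagonal(B, 0.0)
    return BinaryGraph(B=B, r=r, all_zero=not B.any())


def transfer_matrix(graph: BinaryGraph) -> TransferMatrix:
    """Column-stochastic spread of score over links.

    ``deg(u)`` is u's number of links (row sum of B); columns of dangling
    nodes are zero and their indices are recorded.
    """
    B = graph.B
    deg = B.sum(axis=1)
    dangling = tuple(int(i) for i in np.flatnonzero(deg == 0))
    safe = np.where(deg > 0, deg, 1.0)
    T = (B / safe[:, None]).T
    return TransferMatrix(T=T, dangling=dangling)


def pagerank(
    graph: BinaryGraph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> NodeScores:
    """Simplified (damping-free) PageRank: the fixed point of ``s = T s``.

    Starts from the uniform vector, redistributes dangling mass uniformly,
    and applies the lazy half-step ``s <- (s + T s)/2`` until the fixed-point
    residual ``||T s - s||_1`` (dangling mass included) drops below ``tol``.
    The result is nonnegative and sums to one.
    """
    if graph.n_edges == 0:
        raise ValidationError("pagerank needs at least one edge")
    tm = transfer_matrix(graph)
    n = graph.n_nodes
    dang = np.array(tm.dangling, dtype=int)
    s = np.full(n, 1.0 / n)

    for it in range(1, max_iter + 1):
        step = tm.T @ s
        if dang.size:
            step += s[dang].sum() / n
        change = float(np.abs(step - s).sum())
        s = (s + step) / 2.0
        total = float(s.sum())
        if abs(total - 1.0) > 1e-9:  # pragma: no cover - structural invariant
            raise SolverDivergenceError(f"score mass drifted to {total}")
        s /= total
        if change < tol:
            return NodeScores(s=s, method="pagerank", n_iter=it)
    raise SolverDivergenceError(
        f"pagerank did not converge in {max_iter} iterations "
        f"(last change {change:.3e})"
    )


def _undirected(graph: BinaryGraph) -> nx.Graph:
    B = np.maximum(graph.B, graph.B.T)
    return nx.from_numpy_array(B)


def _radiality(g: nx.Graph) -> np.ndarray:
    """Radiality per node: mean over reachable peers of (diam + 1 - d(u, v)),
    computed within each connected component; isolated nodes score 0."""
    n = g.number_of_nodes()
    out = np.zeros(n)
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        for u in comp:
            total = sum(diam + 1 - d for v, d in dist[u].items() if v != u)
            out[u] = total / (len(comp) - 1)
    return out


def node_scores(graph: BinaryGraph, method: str) -> NodeScores:
    """Classical topological importance scores on the undirected graph.

    ``clustering``: local clustering coefficient 2*triangles/(deg*(deg-1));
    ``avgdeg``: node degree; ``closeness``: (n_reachable - 1) / sum of
    shortest-path distances (per connected component); ``radiality``: mean of
    (component diameter + 1 - distance) over reachable peers.
    """
    if method == "pagerank":
        return pagerank(graph)
    if method not in COMPARATOR_METHODS:
        raise ValidationError(
            f"unknown method {method!r}; choose from "
            f"{('pagerank',) + COMPARATOR_METHODS}"
        )
    g = _undirected(graph)
    n = graph.n_nodes
    if method == "clustering":
        vals = nx.clustering(g)
        s = np.array([vals[i] for i in range(n)], dtype=float)
    elif method == "avgdeg":
        s = np.array([g.degree(i) for i in range(n)], dtype=float)
    elif method == "closeness":
        vals = nx.closeness_centrality(g, wf_improved=False)
        s = np.array([vals[i] for i in range(n)], dtype=float)
    else:
        s = _radiality(g)
    return NodeScores(s=s, method=method)
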