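"""Independent oracles used by the tests.

Each oracle computes the same quantity as the package by a different
route (regression residuals, generic convex optimization, exhaustive
path enumeration), so agreement is evidence of correctness rather than
of shared code.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import optimize, stats


def random_correlation_matrix(p: int, rng: np.random.Generator,
                              df_scale: int = 3) -> np.ndarray:
    """Random PD correlation matrix via a Wishart draw standardized to
    unit diagonal."""
    X = rng.standard_normal((df_scale * p, p))
    cov = X.T @ X / (df_scale * p)
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2


def pcor_by_schur(cov: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of (i, j) given all the rest, via the Schur
    complement (equivalently: correlating the least-squares residuals of
    i and j after regression on the remaining variables)."""
    p = cov.shape[0]
    rest = [k for k in range(p) if k not in (i, j)]
    A = cov[np.ix_([i, j], [i, j])]
    if rest:
        B = cov[np.ix_([i, j], rest)]
        C = cov[np.ix_(rest, rest)]
        A = A - B @ np.linalg.solve(C, B.T)
    return A[0, 1] / np.sqrt(A[0, 0] * A[1, 1])


def constrained_mle_by_optimizer(S: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """GGM MLE under a fixed zero pattern by generic smooth optimization.

    Maximizes log det K - tr(S K) over the free entries of K (diagonal +
    modeled off-diagonals) with the analytic gradient K^-1 - S.
    """
    p = S.shape[0]
    ii, jj = np.where(np.triu(adj, 1))

    def unpack(theta):
        K = np.zeros((p, p))
        K[np.diag_indices(p)] = theta[:p]
        K[ii, jj] = theta[p:]
        K[jj, ii] = theta[p:]
        return K

    def negll_and_grad(theta):
        K = unpack(theta)
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e12 + float(np.sum(theta ** 2)), np.zeros_like(theta)
        f = -(logdet - float(np.sum(S * K)))
        G = -(np.linalg.inv(K) - S)
        grad = np.concatenate([np.diag(G), 2 * G[ii, jj]])
        return f, grad

    theta0 = np.concatenate([1.0 / np.diag(S), np.zeros(ii.size)])
    res = optimize.minimize(negll_and_grad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    assert res.success or np.max(np.abs(res.jac)) < 1e-7, res.message
    return unpack(res.x)


def brute_force_shortest(G: nx.Graph, source: str, rel_tol: float = 1e-12):
    """Exhaustive enumeration of all simple paths from the source.

    Returns {target: (min_distance, set of tied node tuples)} using the
    edge attribute ``distance`` as cost.
    """
    out = {}
    for target in G.nodes:
        if target == source:
            continue
        best, tied = np.inf, []
        for path in nx.all_simple_paths(G, source, target):
            d = sum(G.edges[a, b]["distance"] for a, b in zip(path, path[1:]))
            if d < best * (1 - rel_tol):
                best, tied = d, [tuple(path)]
            elif abs(d - best) <= rel_tol * max(best, 1.0):
                tied.append(tuple(path))
        if tied:
            out[target] = (best, set(tied))
    return out


def brute_force_betweenness(G: nx.Graph, source: str) -> dict[str, float]:
    """Fractional source-anchored betweenness from the enumerated tied
    shortest paths: each of the m tied paths to a target credits 1/m to
    every intermediate node."""
    counts = {v: 0.0 for v in G.nodes}
    for target, (_, tied) in brute_force_shortest(G, source).items():
        m = len(tied)
        for path in tied:
            for v in path[1:-1]:
                counts[v] += 1.0 / m
    counts[source] = 0.0
    return counts


def random_weighted_graph(n_nodes: int, rng: np.random.Generator,
                          edge_prob: float = 0.45,
                          allow_negative: bool = True) -> np.ndarray:
    """Random symmetric weight matrix for the path-analytics oracles."""
    W = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                w = rng.uniform(0.1, 0.9)
                if allow_negative and rng.random() < 0.3:
                    w = -w
                W[i, j] = W[j, i] = w
    return W


def spearman_no_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Classical rank formula 1 - 6*sum(d^2)/(n(n^2-1)); valid without ties."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1))
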