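"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: distances come from a
Floyd-Warshall min-plus recursion, core numbers from per-k maximal-subgraph
membership, and regression residuals from the normal equations.
"""

import numpy as np


def floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by the Floyd-Warshall recursion."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    d[a > 0] = 1.0
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def kcore_membership(adjacency: np.ndarray) -> np.ndarray:
    """Core numbers via per-k membership in the maximal subgraph of
    minimum degree >= k (recomputed from scratch for every k)."""
    a = np.asarray(adjacency) > 0
    n = a.shape[0]
    core = np.zeros(n, dtype=int)
    for k in range(1, n):
        alive = np.ones(n, dtype=bool)
        changed = True
        while changed:
            deg = (a & alive[None, :] & alive[:, None]).sum(axis=1)
            drop = alive & (deg < k)
            changed = bool(drop.any())
            alive[drop] = False
        if not alive.any():
            break
        core[alive] = k
    return core


def normal_equations_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals via an explicit normal-equations solve."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return y - x @ beta


def pairwise_pearson(series: np.ndarray) -> np.ndarray:
    """Pearson matrix from the elementwise covariance/SD formula."""
    n, t = series.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = series[i], series[j]
            cov = ((xi - xi.mean()) * (xj - xj.mean())).mean()
            out[i, j] = out[j, i] = cov / (xi.std() * xj.std())
    return out


def erdos_renyi_adjacency(n: int, mean_degree: float, rng: np.random.Generator) -> np.ndarray:
    p = mean_degree / (n - 1)
    iu = np.triu_indices(n, 1)
    a = np.zeros((n, n), dtype=np.int8)
    keep = rng.random(iu[0].size) < p
    a[iu[0][keep], iu[1][keep]] = 1
    return a + a.T
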