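"""Independent brute-force reference implementations used only by the tests.

Everything here is written for clarity, not speed, and deliberately avoids
the package's own code paths: pure-python Floyd-Warshall, exhaustive
shortest-path enumeration, explicit triangle counting, two-pass correlation
sums, textbook one-way ANOVA.
"""

from __future__ import annotations

import math

import numpy as np

INF = math.inf


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """Triple-loop all-pairs shortest distances; lengths 0 = no edge."""
    n = lengths.shape[0]
    D = [[0.0 if i == j else (lengths[i][j] if lengths[i][j] > 0 else INF)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = D[i][k] + D[k][j]
                if alt < D[i][j]:
                    D[i][j] = alt
    return np.array(D)


def enumerate_shortest_paths(lengths: np.ndarray, src: int, dst: int, tol=1e-9):
    """All shortest simple paths src -> dst by DFS over the graph.

    Returns (distance, list of paths as node tuples); distance INF and no
    paths when unreachable.
    """
    n = lengths.shape[0]
    D = floyd_warshall(lengths)
    best = D[src][dst]
    if not math.isfinite(best):
        return INF, []
    paths = []

    def dfs(node, dist, trail):
        if node == dst:
            if abs(dist - best) <= tol * max(1.0, best):
                paths.append(tuple(trail))
            return
        for nxt in range(n):
            if lengths[node][nxt] > 0 and nxt not in trail:
                nd = dist + lengths[node][nxt]
                # prune: only continue along shortest-path prefixes
                if nd + D[nxt][dst] <= best + tol * max(1.0, best):
                    dfs(nxt, nd, trail + [nxt])

    dfs(src, 0.0, [src])
    return best, paths


def betweenness_brute(lengths: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive path enumeration over *unordered* pairs,
    normalized by (n-1)(n-2)."""
    n = lengths.shape[0]
    b = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            _, paths = enumerate_shortest_paths(lengths, h, j)
            if not paths:
                continue
            rho = len(paths)
            for i in range(n):
                if i in (h, j):
                    continue
                rho_i = sum(1 for p in paths if i in p[1:-1])
                b[i] += rho_i / rho
    if n > 2:
        b /= (n - 1) * (n - 2)
    return b


def nodal_efficiency_brute(lengths: np.ndarray) -> np.ndarray:
    D = floyd_warshall(lengths)
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and math.isfinite(D[i][j]) and D[i][j] > 0:
                acc += 1.0 / D[i][j]
        out[i] = acc / (n - 1)
    return out


def global_efficiency_brute(lengths: np.ndarray) -> float:
    return float(np.mean(nodal_efficiency_brute(lengths)))


def clustering_brute_binary(adj: np.ndarray):
    """Triangle counting with explicit loops; returns (C, per-node C_i)."""
    n = adj.shape[0]
    Ci = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        t = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a]][nbrs[b]] > 0:
                    t += 1
        Ci[i] = 2.0 * t / (k * (k - 1))
    return float(np.mean(Ci)), Ci


def clustering_brute_weighted(W: np.ndarray):
    """Onnela geometric-mean clustering with explicit loops."""
    n = W.shape[0]
    wmax = W.max()
    Ci = np.zeros(n)
    if wmax == 0:
        return 0.0, Ci
    for i in range(n):
        nbrs = [j for j in range(n) if W[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for a in nbrs:
            for b in nbrs:
                if a != b and W[a][b] > 0:
                    acc += ((W[i][a] / wmax) * (W[i][b] / wmax) * (W[a][b] / wmax)) ** (1 / 3)
        Ci[i] = acc / (k * (k - 1))
    return float(np.mean(Ci)), Ci


def local_efficiency_brute(lengths: np.ndarray, adj: np.ndarray) -> float:
    """Mean global efficiency of neighbour-induced subgraphs."""
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j] > 0]
        if len(nbrs) < 2:
            continue
        sub = lengths[np.ix_(nbrs, nbrs)]
        total += global_efficiency_brute(sub)
    return total / n


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation (explicit summation formula)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[t] - mx) * (y[t] - my) for t in range(n))
    dx = math.sqrt(sum((x[t] - mx) ** 2 for t in range(n)))
    dy = math.sqrt(sum((y[t] - my) ** 2 for t in range(n)))
    return num / (dx * dy)


def icc_anova_oracle(X: np.ndarray) -> float:
    """One-way ANOVA ICC with explicit sums of squares."""
    n, k = X.shape
    grand = X.mean()
    ss_b = k * sum((X[i].mean() - grand) ** 2 for i in range(n))
    ms_b = ss_b / (n - 1)
    ss_w = sum((X[i][j] - X[i].mean()) ** 2 for i in range(n) for j in range(k))
    ms_w = ss_w / (n * (k - 1))
    return (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)


def random_graph(rng, n: int, mode: str = "binary", p: float = 0.4):
    """Random symmetric adjacency (weights in (0.2, 1] for weighted mode)."""
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p:
                w = 1.0 if mode == "binary" else float(rng.uniform(0.2, 1.0))
                A[i, j] = A[j, i] = w
    return A


def lengths_of(adjacency: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        return (adjacency > 0).astype(float)
    return np.where(adjacency > 0, 1.0 / np.where(adjacency > 0, adjacency, 1.0), 0.0)
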