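"""Independent oracles used by the tests: deliberately naive implementations
that share no code with the package."""

from __future__ import annotations

import itertools

import numpy as np


def ols_var_fit(x: np.ndarray, order: int) -> np.ndarray:
    """Ordinary least squares multichannel AR fit: coeffs (order, n, n)."""
    x = x - x.mean(axis=1, keepdims=True)
    n, T = x.shape
    Y = x[:, order:].T
    X = np.hstack([x[:, order - r : T - r].T for r in range(1, order + 1)])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta.T.reshape(n, order, n).swapaxes(0, 1)


# ---------------------------------------------------------------- graphs ---

def _all_simple_paths(adj, s, t):
    n = adj.shape[0]
    paths = []

    def walk(node, visited, path):
        if node == t:
            paths.append(list(path))
            return
        for v in range(n):
            if adj[node, v] and v not in visited:
                walk(v, visited | {v}, path + [v])

    walk(s, {s}, [s])
    return paths


def bf_distances_and_counts(adj):
    """All-pairs shortest-path lengths, path counts and through-node counts
    by exhaustive simple-path enumeration."""
    n = adj.shape[0]
    dist = np.full((n, n), -1)
    sigma = np.zeros((n, n))
    through = np.zeros((n, n, n))  # [s, t, v]
    for s in range(n):
        dist[s, s] = 0
        for t in range(n):
            if t == s:
                continue
            paths = _all_simple_paths(adj, s, t)
            if not paths:
                continue
            dmin = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == dmin]
            dist[s, t] = dmin
            sigma[s, t] = len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    through[s, t, v] += 1
    return dist, sigma, through


def bf_node_metrics(adj):
    """The six node metrics, brute force, same conventions as the package:
    clustering/local efficiency 0 for degree < 2, APL over reachable nodes
    only, betweenness normalized by (n-1)(n-2)/2."""
    adj = (np.asarray(adj) != 0).astype(int)
    n = adj.shape[0]
    dist, sigma, through = bf_distances_and_counts(adj)
    out = {k: np.zeros(n) for k in
           ("degree", "cost", "clustering", "local_efficiency",
            "betweenness", "avg_path_length")}
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        out["degree"][i] = k
        out["cost"][i] = k / (n - 1) if n > 1 else 0.0
        if k >= 2:
            e = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
            out["clustering"][i] = e / (k * (k - 1) / 2)
            sub = adj[np.ix_(nb, nb)]
            dsub, _, _ = bf_distances_and_counts(sub)
            acc = 0.0
            for a in range(k):
                for b in range(k):
                    if a != b and dsub[a, b] > 0:
                        acc += 1.0 / dsub[a, b]
            out["local_efficiency"][i] = acc / (k * (k - 1))
        reach = [dist[i, t] for t in range(n) if t != i and dist[i, t] > 0]
        out["avg_path_length"][i] = float(np.mean(reach)) if reach else 0.0
        bt = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s != i and t != i and sigma[s, t] > 0:
                    bt += through[s, t, i] / sigma[s, t]
        norm = (n - 1) * (n - 2) / 2
        out["betweenness"][i] = bt / norm if norm > 0 else 0.0
    return out


def all_graphs(n):
    """Every undirected simple graph on n labelled nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n), dtype=int)
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                adj[i, j] = adj[j, i] = 1
        yield adj


# -------------------------------------------------------------- rank sums ---

def exact_mannwhitney_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of the null
    assignments of pooled observations to the two groups (tie-free data)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pooled.argsort().argsort() + 1  # tie-free
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    idx = range(len(pooled))
    us = []
    allranks = np.sort(ranks)
    for comb in itertools.combinations(idx, n1):
        r = allranks[list(comb)]
        us.append(np.sum(r) - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))
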