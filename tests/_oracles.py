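"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (path enumeration, power iteration,
exhaustive sweeps) kept free of the package's own code paths so they can
serve as a second route for cross-checking.
"""

from collections import deque
from itertools import combinations

import numpy as np

Adjacency = dict[str, set[str]]


def adjacency_of(nodes, edges) -> Adjacency:
    adj: Adjacency = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj: Adjacency, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def _all_simple_paths(adj: Adjacency, s: str, t: str, limit: int):
    """Every simple path from s to t with at most ``limit`` edges."""
    out = []
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            out.append(path)
            continue
        if len(path) - 1 >= limit:
            continue
        for w in adj[u]:
            if w not in path:
                stack.append((w, path + [w]))
    return out


def brute_degree(adj: Adjacency) -> dict[str, float]:
    return {v: float(len(adj[v])) for v in adj}


def brute_betweenness(adj: Adjacency) -> dict[str, float]:
    """Unnormalized pair-dependency by full shortest-path enumeration."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        shortest = [p for p in _all_simple_paths(adj, s, t, dist[t])
                    if len(p) - 1 == dist[t]]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    return bc


def brute_closeness(adj: Adjacency) -> dict[str, float]:
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_eigenvector(adj: Adjacency, iters: int = 10_000) -> dict[str, float]:
    """Power iteration on A + I, L2-normalized, positive orientation."""
    nodes = sorted(adj)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for v in nodes:
        for w in adj[v]:
            A[index[v], index[w]] = 1.0
    x = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        nxt = (A + np.eye(n)) @ x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.linalg.norm(nxt - x) < 1e-14:
            x = nxt
            break
        x = nxt
    if x.sum() < 0:
        x = -x
    return {v: float(x[index[v]]) for v in nodes}


def brute_ecc(adj: Adjacency, u: str, v: str) -> float:
    denom = min(len(adj[u]), len(adj[v])) - 1
    if denom <= 0:
        return 0.0
    return len(adj[u] & adj[v]) / denom


def brute_nc(adj: Adjacency) -> dict[str, float]:
    return {v: sum(brute_ecc(adj, v, u) for u in adj[v]) for v in adj}


def brute_lac(adj: Adjacency) -> dict[str, float]:
    out = {}
    for v in adj:
        nbrs = adj[v]
        if not nbrs:
            out[v] = 0.0
            continue
        out[v] = sum(len(adj[u] & nbrs) for u in nbrs) / len(nbrs)
    return out


def brute_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def brute_pec(adj: Adjacency, expr) -> dict[str, float]:
    return {v: sum(brute_ecc(adj, v, u) * max(0.0, brute_pearson(expr[v], expr[u]))
                   for u in adj[v])
            for v in adj}


def brute_wdc(adj: Adjacency, expr, lam: float = 0.5) -> dict[str, float]:
    return {v: sum(lam * brute_ecc(adj, v, u)
                   + (1 - lam) * max(0.0, brute_pearson(expr[v], expr[u]))
                   for u in adj[v])
            for v in adj}


# ---------------------------------------------------------------------------
# metric oracles


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney by exhaustive pair comparison, ties get half credit."""
    pos = [scores[i] for i, y in enumerate(labels) if y == 1]
    neg = [scores[i] for i, y in enumerate(labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def sweep_average_precision(scores, labels) -> float:
    """AP = sum over descending thresholds of (dR) * P (step-wise)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores, dtype=float)[order]
    n_pos = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    # thresholds at each distinct score value
    i = 0
    tp = fp = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


# ---------------------------------------------------------------------------
# random small graphs


def random_connected_graph(rng: np.random.Generator,
                           min_n: int = 3, max_n: int = 7):
    """A random connected simple graph: spanning tree + random extra edges."""
    n = int(rng.integers(min_n, max_n + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):
        a = nodes[order[i]]
        b = nodes[order[int(rng.integers(0, i))]]
        edges.add(tuple(sorted((a, b))))
    possible = [tuple(sorted(p)) for p in combinations(nodes, 2)]
    for pair in possible:
        if pair not in edges and rng.random() < 0.3:
            edges.add(pair)
    return nodes, sorted(edges)
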