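"""Independent brute-force oracles for graph metrics and statistics.

Everything here is written from first principles on adjacency matrices and
explicit enumeration (no networkx, no reuse of the package's code paths),
so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_degree(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1)


def bf_clustering(a: np.ndarray) -> np.ndarray:
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            a[u, v] for u, v in itertools.combinations(nbrs, 2)
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def bf_transitivity(a: np.ndarray) -> float:
    n = len(a)
    triangles = sum(
        a[i, j] * a[j, k] * a[i, k]
        for i, j, k in itertools.combinations(range(n), 3)
    )
    triads = sum(
        int(d * (d - 1) / 2) for d in a.sum(axis=1).astype(int)
    )
    return 3.0 * triangles / triads if triads else 0.0


def bf_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by Floyd–Warshall."""
    n = len(a)
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def bf_cpl_efficiency(a: np.ndarray) -> tuple[float, float]:
    n = len(a)
    d = bf_distances(a)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    cpl = d[finite].mean() if finite.any() else 0.0
    inv = np.where(finite, 1.0 / np.where(d == 0, 1, d), 0.0)
    eff = inv[off].sum() / (n * (n - 1))
    return float(cpl), float(eff)


def bf_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = bf_cpl_efficiency(sub)[1]
    return out


def _all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Enumerate every shortest s→t path (BFS levels + DFS back-walk)."""
    n = len(a)
    dist = bf_distances(a)
    if not np.isfinite(dist[s, t]):
        return []
    paths = []

    def walk(node, acc):
        if node == t:
            paths.append(acc)
            return
        for nxt in np.flatnonzero(a[node]):
            if dist[s, nxt] == dist[s, node] + 1 and dist[nxt, t] == dist[node, t] - 1:
                walk(nxt, acc + [int(nxt)])

    walk(s, [s])
    return paths


def bf_betweenness(a: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    n = len(a)
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(a, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def bf_components(a: np.ndarray) -> list[list[int]]:
    n = len(a)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(int(u) for u in np.flatnonzero(a[v]))
        comps.append(sorted(comp))
    return comps


def bf_eigenvector(a: np.ndarray, tol: float = 1e-14, max_iter: int = 500_000) -> np.ndarray:
    """Principal eigenvector on the largest component by power iteration on
    A + I (the shift makes the dominant eigenvalue strictly dominant even
    for bipartite components)."""
    comps = sorted(bf_components(a), key=lambda c: (-len(c), c[0]))
    giant = comps[0]
    out = np.zeros(len(a))
    if len(giant) < 2:
        return out
    sub = a[np.ix_(giant, giant)] + np.eye(len(giant))
    v = np.full(len(giant), 1.0 / np.sqrt(len(giant)))
    for _ in range(max_iter):
        w = sub @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    out[giant] = v / np.linalg.norm(v)
    return out


def bf_participation(a: np.ndarray, modules: np.ndarray) -> np.ndarray:
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        k = a[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(modules):
            k_im = a[i, modules == m].sum()
            acc += (k_im / k) ** 2
        out[i] = 1.0 - acc
    return out


def bf_within_module_z(a: np.ndarray, modules: np.ndarray) -> np.ndarray:
    n = len(a)
    wd = np.array(
        [a[i, modules == modules[i]].sum() for i in range(n)]
    )
    out = np.zeros(n)
    for m in np.unique(modules):
        idx = np.flatnonzero(modules == m)
        mu, sd = wd[idx].mean(), wd[idx].std()
        if sd > 0:
            out[idx] = (wd[idx] - mu) / sd
    return out


def bf_assortativity(a: np.ndarray) -> float:
    """Degree correlation over the 2E ordered endpoint pairs; NaN when
    degenerate."""
    deg = a.sum(axis=1)
    xs, ys = [], []
    n = len(a)
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def bf_modularity(a: np.ndarray, partition: list[set[int]]) -> float:
    two_m = a.sum()
    deg = a.sum(axis=1)
    q = 0.0
    for comm in partition:
        for i in comm:
            for j in comm:
                q += a[i, j] - deg[i] * deg[j] / two_m
    return q / two_m


def bf_best_partition(a: np.ndarray):
    """Exhaustive modularity maximization over all set partitions (small n)."""
    n = len(a)

    def set_partitions(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for part in set_partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1 :]
            yield part + [{first}]

    best_q, best = -np.inf, None
    for part in set_partitions(list(range(n))):
        q = bf_modularity(a, part)
        if q > best_q:
            best_q, best = q, part
    return best, best_q


def bf_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive pair counting, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def permutation_welch_p(a, b, n_perm: int = 20_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Welch t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def welch_t(x, y):
        return (x.mean() - y.mean()) / np.sqrt(
            x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)
        )

    obs = abs(welch_t(a, b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(welch_t(perm[: len(a)], perm[len(a) :])) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def random_binary_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric adjacency of a G(n, p) draw."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1).astype(float)
    return a + a.T
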