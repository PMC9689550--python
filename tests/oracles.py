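"""Independent brute-force implementations used only as test oracles.

Deliberately naive: BFS over adjacency dicts, explicit shortest-path
counting via the distance-matrix pair formula, and a dense symmetric
eigendecomposition.  They share no code path with the package.
"""

from collections import deque

import numpy as np


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def distance_and_path_counts(adj, nodes):
    """All-pairs BFS distances and shortest-path counts (sigma)."""
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        order = deque([s])
        while order:
            u = order.popleft()
            for w in adj[u]:
                if np.isinf(dist[si, index[w]]):
                    dist[si, index[w]] = dist[si, index[u]] + 1
                    order.append(w)
                if dist[si, index[w]] == dist[si, index[u]] + 1:
                    sigma[si, index[w]] += sigma[si, index[u]]
    return dist, sigma


def degree_oracle(adj, nodes):
    n = len(nodes)
    return {v: len(adj[v]) / (n - 1) for v in nodes}


def closeness_oracle(adj, nodes, conventional=False):
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        comp_size = len(dist)
        if comp_size == 1:
            out[v] = 0.0
            continue
        numer = comp_size - 1 if conventional else comp_size
        out[v] = numer / sum(dist.values())
    return out


def betweenness_oracle(adj, nodes):
    """BC_i over unordered pairs via the sigma pair formula.

    A node i lies on a shortest s-t path iff d(s,i) + d(i,t) = d(s,t);
    the number of such paths is sigma(s,i) * sigma(i,t).
    """
    dist, sigma = distance_and_path_counts(adj, nodes)
    n = len(nodes)
    bc = {}
    for k, v in enumerate(nodes):
        total = 0.0
        for s in range(n):
            if s == k:
                continue
            for t in range(s + 1, n):  # unordered pairs
                if t == k or np.isinf(dist[s, t]):
                    continue
                if dist[s, k] + dist[k, t] == dist[s, t]:
                    total += sigma[s, k] * sigma[k, t] / sigma[s, t]
        bc[v] = total
    return bc


def eigenvector_oracle(adj, nodes):
    """Principal eigenvector of the largest component via numpy.linalg.eigh."""
    comps = []
    seen = set()
    for v in nodes:
        if v not in seen:
            comp = set(bfs_distances(adj, v))
            seen |= comp
            comps.append(comp)
    comp = sorted(min(comps, key=lambda c: (-len(c), min(c))))
    out = {v: 0.0 for v in nodes}
    if len(comp) == 1:
        out[comp[0]] = 1.0
        return out
    a = np.zeros((len(comp), len(comp)))
    pos = {v: i for i, v in enumerate(comp)}
    for v in comp:
        for w in adj[v]:
            a[pos[v], pos[w]] = 1.0
    vals, vecs = np.linalg.eigh(a)
    x = vecs[:, np.argmax(vals)]
    x = np.abs(x)
    x /= np.linalg.norm(x)
    out.update(zip(comp, x.tolist()))
    return out


def random_graph(rng, n_max=60):
    """A random simple graph (sometimes disconnected) as (nodes, edges)."""
    n = int(rng.integers(3, n_max + 1))
    nodes = [f"N{i:02d}" for i in range(n)]
    p = float(rng.uniform(0.03, 0.35))
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return nodes, edges
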