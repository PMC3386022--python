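"""Brute-force reference implementations used as independent test oracles.

Everything here is deliberately naive: explicit breadth-first searches,
explicit enumeration of shortest paths and of subsets, exact rational
arithmetic.  None of it shares code with the package implementation.
"""

from collections import deque
from fractions import Fraction
from itertools import combinations

import numpy as np


def bfs_distances(nodes, edges, source):
    """Hop distances from source over directed edges; unreachable absent."""
    adj = {n: [] for n in nodes}
    for s, t in edges:
        adj[s].append(t)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def enumerate_shortest_paths(nodes, edges, s, t):
    """All shortest directed paths s -> t, as node tuples; [] if unreachable."""
    if s == t:
        return []
    d_from_s = bfs_distances(nodes, edges, s)
    if t not in d_from_s:
        return []
    rev = [(b, a) for a, b in edges]
    d_to_t = bfs_distances(nodes, rev, t)
    target_len = d_from_s[t]
    adj = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
    paths = []

    def walk(u, path):
        used = len(path) - 1
        if u == t:
            paths.append(tuple(path))
            return
        for w in adj[u]:
            if d_from_s.get(w) == used + 1 and d_to_t.get(w) == target_len - used - 1:
                walk(w, path + [w])

    walk(s, [s])
    return paths


def betweenness_by_enumeration(nodes, edges):
    """Unnormalised betweenness: fractional count of shortest paths through v."""
    score = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = enumerate_shortest_paths(nodes, edges, s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    score[v] += w
    return score


def closeness_by_bfs(nodes, edges):
    """(number reachable from v) / (sum of distances from v); 0 for sinks."""
    out = {}
    for v in nodes:
        dist = bfs_distances(nodes, edges, v)
        dist.pop(v)
        out[v] = len(dist) / sum(dist.values()) if dist else 0.0
    return out


def regulator_distances_by_bfs(nodes, edges_with_mode):
    """Mean BFS distance from every 'expression'-out-edge node that reaches v."""
    regulators = {s for s, _, mode in edges_with_mode if mode == "expression"}
    plain = [(s, t) for s, t, _ in edges_with_mode]
    sums, counts = {}, {}
    for r in regulators:
        for v, d in bfs_distances(nodes, plain, r).items():
            if v in regulators:
                continue
            sums[v] = sums.get(v, 0) + d
            counts[v] = counts.get(v, 0) + 1
    return {v: sums[v] / counts[v] for v in sums}


def random_digraph(rng, max_nodes=8, edge_prob=0.3, expression_prob=0.0):
    """Random directed graph as (nodes, mode-labelled edges)."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < edge_prob:
                mode = "expression" if rng.random() < expression_prob else "binding"
                edges.append((a, b, mode))
    return nodes, edges


def hypergeom_tail_by_enumeration(universe_n, pathway_k, query_n):
    """Exact P[overlap >= x] for all x, by enumerating every size-n subset."""
    universe = range(universe_n)
    pathway = set(range(pathway_k))
    total = 0
    hist = [0] * (min(pathway_k, query_n) + 1)
    for subset in combinations(universe, query_n):
        hist[len(pathway.intersection(subset))] += 1
        total += 1
    tails = []
    acc = 0
    for x in range(len(hist) - 1, -1, -1):
        acc += hist[x]
        tails.append(Fraction(acc, total))
    tails.reverse()
    return tails  # tails[x] = P[X >= x]
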