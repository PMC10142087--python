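"""Independent brute-force oracles used to cross-check the graph statistics.

These deliberately avoid the library's code paths (and networkx's clique
machinery): cliques come from all-subsets enumeration, components from a
hand-rolled flood fill.
"""

from __future__ import annotations

import math
from itertools import combinations


def _is_clique(nodes: tuple, edges: set[frozenset]) -> bool:
    return all(frozenset((a, b)) in edges for a, b in combinations(nodes, 2))


def brute_maximal_cliques(nodes: list, edge_pairs: list[tuple]) -> list[frozenset]:
    """Every maximal clique by checking all vertex subsets (n <= ~15)."""
    edges = {frozenset(e) for e in edge_pairs}
    cliques = []
    node_set = set(nodes)
    for r in range(1, len(nodes) + 1):
        for sub in combinations(sorted(nodes), r):
            if not _is_clique(sub, edges):
                continue
            extendable = any(
                _is_clique(sub + (v,), edges) for v in node_set - set(sub)
            )
            if not extendable:
                cliques.append(frozenset(sub))
    return cliques


def brute_mcc(nodes: list, edge_pairs: list[tuple]) -> dict:
    scores = {v: 0 for v in nodes}
    for clique in brute_maximal_cliques(nodes, edge_pairs):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def brute_degree(nodes: list, edge_pairs: list[tuple]) -> dict:
    scores = {v: 0 for v in nodes}
    for a, b in edge_pairs:
        scores[a] += 1
        scores[b] += 1
    return scores


def brute_mnc(nodes: list, edge_pairs: list[tuple]) -> dict:
    """Largest component of each node's neighbor-induced subgraph, by flood
    fill over an adjacency dict built from scratch."""
    adj: dict = {v: set() for v in nodes}
    for a, b in edge_pairs:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        nbrs = adj[v]
        best, seen = 0, set()
        for start in nbrs:
            if start in seen:
                continue
            comp, stack = set(), [start]
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] & nbrs - comp)
            seen |= comp
            best = max(best, len(comp))
        out[v] = best
    return out


def random_graph(rng, n_nodes: int, p: float) -> tuple[list, list[tuple]]:
    """Erdos-Renyi edge list over string node labels."""
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    edges = [(a, b) for a, b in combinations(nodes, 2) if rng.random() < p]
    return nodes, edges
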