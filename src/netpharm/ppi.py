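"""Protein-protein interaction network construction and hub ranking.

Builds an undirected simple graph from a STRING-style scored edge list and
ranks nodes by the three cytoHubba-style centralities used for hub-gene
discovery:

* **Degree** — ``Deg(v) = |N(v)|``, the neighbor count.
* **MNC** (Maximum Neighborhood Component) — the size of the largest
  connected component of the subgraph induced by ``N(v)`` (``v`` excluded).
* **MCC** (Maximal Clique Centrality) — ``sum over maximal cliques C
  containing v of (|C| - 1)!``.  An isolated node forms its own singleton
  maximal clique and scores ``0! = 1``.

For every node ``MCC(v) >= Deg(v) >= MNC(v)``: each neighbor lies in at
least one maximal clique with ``v`` and ``(c-1)! >= c-1``, and a component of
the neighbor subgraph can never exceed the neighbor count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "NetworkStats",
    "HubRanking",
    "load_interaction_table",
    "network_stats",
    "degree_score",
    "mnc_score",
    "mcc_score",
    "enumerate_maximal_cliques",
    "rank_nodes",
    "consensus_top",
    "HUB_METHODS",
]

HUB_METHODS = ("MCC", "MNC", "Degree")

#: Default STRING-style confidence cutoff ("medium confidence").
DEFAULT_MIN_CONFIDENCE = 0.400


@dataclass(frozen=True)
class NetworkStats:
    """Topology summary of an interaction network.

    ``average_neighbors`` is 2E/N rounded to 3 decimals; diameter and radius
    are unweighted eccentricity extremes on the largest connected component
    (the rule only matters for disconnected inputs).
    """

    n_nodes: int
    n_edges: int
    average_neighbors: float
    diameter: int
    radius: int

    def as_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "average_neighbors": self.average_neighbors,
            "diameter": self.diameter,
            "radius": self.radius,
        }


@dataclass(frozen=True)
class HubRanking:
    """Top-k nodes under one centrality, scores non-increasing."""

    method: str
    entries: tuple[tuple[str, float], ...]

    def top(self, k: int) -> list[str]:
        return [g for g, _ in self.entries[:k]]


def load_interaction_table(
    rows: pd.DataFrame | Iterable[tuple],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    include_nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Build a simple undirected graph from a scored edge list.

    Scores may be on the STRING integer 0-1000 scale or already in [0, 1];
    any value above 1 switches on the 0-1000 interpretation and all scores
    are divided by 1000.  The confidence cutoff is applied after scaling and
    is inclusive (a 400/1000 edge survives a 0.400 cutoff).  Self-loops are
    dropped; duplicate or reversed pairs collapse, keeping the maximum
    score.  ``include_nodes`` adds (possibly isolated) query nodes.
    """
    if isinstance(rows, pd.DataFrame):
        triples = list(rows.itertuples(index=False, name=None))
    else:
        triples = list(rows)

    for t in triples:
        if len(t) < 3:
            raise ValueError(f"malformed edge row (need node, node, score): {t!r}")

    scores = [float(t[2]) for t in triples]
    if any(s < 0 for s in scores):
        raise ValueError("negative interaction scores are not allowed")
    scale = 1000.0 if any(s > 1 for s in scores) else 1.0

    best: dict[tuple[str, str], float] = {}
    for (a, b, s, *_) in triples:
        a, b = str(a), str(b)
        if a == b:
            continue  # self-loop
        key = (a, b) if a <= b else (b, a)
        s = float(s) / scale
        if s > best.get(key, -1.0):
            best[key] = s

    g = nx.Graph()
    if include_nodes is not None:
        g.add_nodes_from(include_nodes)
    for (a, b), s in best.items():
        if s >= min_confidence:
            g.add_edge(a, b, confidence=s)
    return g


def network_stats(net: nx.Graph) -> NetworkStats:
    """Node/edge counts, average neighbors, and largest-component
    diameter/radius."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        raise ValueError("network is empty")
    avg = round(2 * e / n, 3)
    giant = net.subgraph(max(nx.connected_components(net), key=len))
    ecc = nx.eccentricity(giant)
    return NetworkStats(n, e, avg, max(ecc.values()), min(ecc.values()))


def _require_node(net: nx.Graph, v: str) -> None:
    if v not in net:
        raise KeyError(f"node {v!r} not in network")


def degree_score(net: nx.Graph, v: str) -> int:
    """Neighbor count of ``v``."""
    _require_node(net, v)
    return net.degree(v)


def mnc_score(net: nx.Graph, v: str) -> int:
    """Size of the largest connected component of the neighbor-induced
    subgraph of ``v`` (``v`` itself excluded); 0 for an isolated node."""
    _require_node(net, v)
    nbrs = list(net.neighbors(v))
    if not nbrs:
        return 0
    sub = net.subgraph(nbrs)
    return max(len(c) for c in nx.connected_components(sub))


def enumerate_maximal_cliques(net: nx.Graph) -> list[frozenset[str]]:
    """All maximal cliques (pivoting Bron-Kerbosch via networkx), each once.

    Isolated nodes appear as singleton cliques.
    """
    return [frozenset(c) for c in nx.find_cliques(net)]


def mcc_score(net: nx.Graph, v: str) -> int:
    """Sum of (|C|-1)! over the maximal cliques C containing ``v``."""
    _require_node(net, v)
    return sum(
        math.factorial(len(c) - 1) for c in nx.find_cliques(net, nodes=[v])
    )


_SCORERS = {"MCC": mcc_score, "MNC": mnc_score, "Degree": degree_score}


def _all_scores(net: nx.Graph, method: str) -> dict[str, float]:
    if method not in _SCORERS:
        raise ValueError(f"unknown method {method!r}; expected one of {HUB_METHODS}")
    if method == "MCC":
        # one clique sweep for the whole graph instead of per-node calls
        scores = {v: 0 for v in net.nodes}
        for clique in nx.find_cliques(net):
            contrib = math.factorial(len(clique) - 1)
            for v in clique:
                scores[v] += contrib
        return scores
    scorer = _SCORERS[method]
    return {v: scorer(net, v) for v in net.nodes}


def rank_nodes(net: nx.Graph, method: str, k: int) -> HubRanking:
    """Top-``k`` nodes under ``method``; ties broken by ascending symbol."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = _all_scores(net, method)
    if k > len(scores):
        warnings.warn(
            f"k={k} exceeds node count {len(scores)}; returning all nodes",
            stacklevel=2,
        )
        k = len(scores)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return HubRanking(method, tuple((g, float(s)) for g, s in ordered))


def consensus_top(rankings: Sequence[HubRanking], k: int) -> list[str]:
    """Genes present in the top-``k`` of every ranking, sorted."""
    if not rankings:
        raise ValueError("need at least one ranking")
    common = set(rankings[0].top(k))
    for r in rankings[1:]:
        common &= set(r.top(k))
    return sorted(common)
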