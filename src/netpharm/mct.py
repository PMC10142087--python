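"""Mushroom-compound-target (M-C-T) tripartite network.

Role-labeled undirected network with one mushroom node, one node per
compound that hits at least one common target, and one node per covered
common target.  Edges are restricted to mushroom-compound (structural
provenance) and compound-target (predicted association); compounds are
prioritized by their count of distinct target neighbors, the mushroom edge
excluded so the reported degree equals the target count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = ["RoleCounts", "build_mct", "mct_counts", "top_compounds_by_degree", "mct_tables"]

ROLES = ("mushroom", "compound", "target")


@dataclass(frozen=True)
class RoleCounts:
    mushrooms: int
    compounds: int
    targets: int
    edges: int

    @property
    def nodes(self) -> int:
        return self.mushrooms + self.compounds + self.targets


def build_mct(
    mushroom_id: str,
    associations: pd.DataFrame | Iterable[tuple[str, str]],
    common: Iterable[str],
) -> nx.Graph:
    """Assemble the tripartite network from deduplicated associations.

    Only links into ``common`` are kept; compounds with no such link are
    excluded entirely (the orphan rule).  Every retained compound is wired
    to the single mushroom node.

    Raises
    ------
    ValueError
        If the common target set is empty.
    """
    common_set = set(common)
    if not common_set:
        raise ValueError("common target set is empty; nothing to assemble")
    if isinstance(associations, pd.DataFrame):
        pairs = set(zip(associations["compound_id"], associations["gene_symbol"]))
    else:
        pairs = set(associations)

    g = nx.Graph()
    g.add_node(mushroom_id, role="mushroom")
    for comp, gene in sorted(pairs):
        if gene not in common_set:
            continue
        if comp not in g:
            g.add_node(comp, role="compound")
            g.add_edge(mushroom_id, comp, kind="mushroom-compound")
        if gene not in g:
            g.add_node(gene, role="target")
        g.add_edge(comp, gene, kind="compound-target")
    return g


def mct_counts(net: nx.Graph) -> RoleCounts:
    """Role-wise node counts and total edge count."""
    roles = nx.get_node_attributes(net, "role")
    counts = {r: 0 for r in ROLES}
    for r in roles.values():
        counts[r] += 1
    return RoleCounts(counts["mushroom"], counts["compound"], counts["target"],
                      net.number_of_edges())


def top_compounds_by_degree(net: nx.Graph, k: int) -> list[tuple[str, int]]:
    """Compounds ranked by distinct target neighbors, descending; ties by
    ascending id.  ``k`` beyond the compound count returns the full list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    roles = nx.get_node_attributes(net, "role")
    scores = []
    for node, role in roles.items():
        if role != "compound":
            continue
        deg = sum(1 for nb in net.neighbors(node) if roles.get(nb) == "target")
        scores.append((node, deg))
    scores.sort(key=lambda kv: (-kv[1], kv[0]))
    return scores[:k]


def mct_tables(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for export to graph-visualization tools."""
    roles = nx.get_node_attributes(net, "role")
    nodes = pd.DataFrame(
        [(n, roles[n], net.degree(n)) for n in sorted(net.nodes)],
        columns=["id", "role", "degree"],
    )
    edges = pd.DataFrame(
        [(a, b, d.get("kind", "")) for a, b, d in sorted(net.edges(data=True))],
        columns=["source", "target", "kind"],
    )
    return nodes, edges
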