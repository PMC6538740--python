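"""Interaction-network construction, intersection and hub extraction.

Networks are undirected simple graphs (:class:`networkx.Graph`) whose
nodes carry a ``kind`` attribute (``compound``, ``target`` or
``protein``).  Hub extraction follows the median-threshold convention of
network pharmacology: compute degree (DC), normalised betweenness (BC),
closeness (CC) and mean neighbour degree (NC, "network centrality") for
every node, then keep nodes strictly above the network medians of DC, BC
and CC.  NC is reported but not part of the default filter because the
published cut-offs are the three medians of DC/BC/CC; a flag adds the NC
median as a fourth condition.

Closeness uses the Wasserman-Faust adjustment (per-component closeness
scaled by the component's share of the graph) so values remain
comparable on disconnected graphs; betweenness is normalised by
``(n-1)(n-2)/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "HubCriteria",
    "build_bipartite",
    "build_ppi",
    "intersect_networks",
    "merge_networks",
    "centralities",
    "extract_hubs",
]


def build_bipartite(
    compound_ids: Iterable[str], mapping: Mapping[str, Iterable[str]]
) -> nx.Graph:
    """Compound-target bipartite network from a compound→targets mapping."""
    g = nx.Graph()
    for cid in compound_ids:
        targets = list(mapping.get(cid, ()))
        if not targets:
            continue
        g.add_node(cid, kind="compound")
        for t in targets:
            g.add_node(t, kind="target")
            g.add_edge(cid, t)
    return g


def build_ppi(
    seed_ids: Iterable[str],
    edges: Iterable[tuple[str, str]],
    expand_neighbors: bool = True,
) -> nx.Graph:
    """Protein-protein interaction network around a seed set.

    With ``expand_neighbors`` (default) the network contains the seeds
    plus all their direct interactors, with every edge of the edge list
    whose endpoints are both included; otherwise the induced subgraph on
    the seeds alone.  Self-loops are dropped and duplicate edges
    deduplicated.  Seeds absent from the edge list are retained as
    isolated nodes with a warning.
    """
    seeds = set(seed_ids)
    full = nx.Graph()
    for a, b in edges:
        if a == b:
            continue
        full.add_edge(a, b)

    if expand_neighbors:
        nodes = set(seeds)
        for s in seeds:
            if s in full:
                nodes.update(full.neighbors(s))
    else:
        nodes = seeds

    g = nx.Graph()
    g.add_nodes_from(nodes, kind="protein")
    g.add_edges_from(
        (a, b) for a, b in full.edges if a in nodes and b in nodes
    )
    orphans = sorted(s for s in seeds if s not in full)
    if orphans:
        warnings.warn(
            f"{len(orphans)} seed(s) absent from the edge list kept as "
            f"isolated nodes: {orphans[:10]}",
            stacklevel=2,
        )
    return g


def _copy_kinds(dst: nx.Graph, *srcs: nx.Graph) -> None:
    for src in srcs:
        for node, data in src.nodes(data=True):
            if node in dst and "kind" in data and "kind" not in dst.nodes[node]:
                dst.nodes[node]["kind"] = data["kind"]


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Node-id and edge-set intersection of two networks."""
    nodes = set(a.nodes) & set(b.nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        (u, v) for u, v in a.edges if u in nodes and v in nodes and b.has_edge(u, v)
    )
    _copy_kinds(g, a, b)
    return g


def merge_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Node and edge union of two networks (the alternative semantics)."""
    g = nx.Graph()
    g.add_nodes_from(a.nodes)
    g.add_nodes_from(b.nodes)
    g.add_edges_from(a.edges)
    g.add_edges_from(b.edges)
    _copy_kinds(g, a, b)
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node centrality table with columns ``dc, bc, cc, nc``.

    dc: degree (integer).  bc: shortest-path betweenness normalised by
    (n-1)(n-2)/2.  cc: closeness with the Wasserman-Faust adjustment.
    nc: arithmetic mean of neighbour degrees (0 for isolated nodes).
    The table medians used as hub cut-offs are stored in
    ``table.attrs["medians"]``.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty graph")
    bc = nx.betweenness_centrality(net, normalized=True)
    cc = nx.closeness_centrality(net, wf_improved=True)
    deg = dict(net.degree())
    nc = {
        v: (sum(deg[u] for u in net.neighbors(v)) / deg[v]) if deg[v] else 0.0
        for v in net.nodes
    }
    table = pd.DataFrame(
        {
            "dc": pd.Series(deg, dtype=int),
            "bc": pd.Series(bc),
            "cc": pd.Series(cc),
            "nc": pd.Series(nc),
        }
    ).sort_index()
    table.index.name = "node"
    table.attrs["medians"] = {c: float(table[c].median()) for c in table.columns}
    return table


@dataclass(frozen=True)
class HubCriteria:
    """Cut-offs for median-threshold hub extraction.

    ``None`` cut-offs default to the centrality table's own medians.
    Comparison is strict-greater.  ``include_nc`` adds mean neighbour
    degree as a fourth condition.
    """

    dc_cutoff: float | None = None
    bc_cutoff: float | None = None
    cc_cutoff: float | None = None
    nc_cutoff: float | None = None
    include_nc: bool = False


def extract_hubs(
    table: pd.DataFrame, criteria: HubCriteria | None = None
) -> tuple[set[str], dict[str, float]]:
    """Nodes strictly above every cut-off (default: the table medians).

    Returns the hub id set and a report of the cut-offs actually used.
    """
    if table.empty:
        raise ValueError("centrality table is empty")
    criteria = criteria or HubCriteria()
    medians = table.attrs.get(
        "medians", {c: float(table[c].median()) for c in ("dc", "bc", "cc", "nc")}
    )
    cuts = {
        "dc": criteria.dc_cutoff if criteria.dc_cutoff is not None else medians["dc"],
        "bc": criteria.bc_cutoff if criteria.bc_cutoff is not None else medians["bc"],
        "cc": criteria.cc_cutoff if criteria.cc_cutoff is not None else medians["cc"],
    }
    mask = (
        (table["dc"] > cuts["dc"])
        & (table["bc"] > cuts["bc"])
        & (table["cc"] > cuts["cc"])
    )
    if criteria.include_nc:
        cuts["nc"] = (
            criteria.nc_cutoff if criteria.nc_cutoff is not None else medians["nc"]
        )
        mask &= table["nc"] > cuts["nc"]
    return set(table.index[mask]), cuts
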