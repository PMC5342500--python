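"""Anchor-centered subnetwork extraction and key-driver analysis.

From a directed (consensus or super) network, the union of all tied
shortest directed paths from the anchor gene to each member of a target
gene set defines the anchor-to-target subnetwork; unreachable targets
are reported separately. Downstream k-layer neighborhoods (all nodes
within k directed steps) are tested for enrichment of perturbation
signatures layer by layer, and key-driver analysis ranks every node by
the Fisher-exact enrichment of its h-layer downstream neighborhood for
a target gene set (BH-adjusted across nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .exprstats import bh_adjust, fisher_enrichment

__all__ = [
    "Subnetwork",
    "shortest_path_subnetwork",
    "downstream_neighborhood",
    "layer_enrichment_profile",
    "key_driver_analysis",
]


@dataclass(frozen=True)
class Subnetwork:
    """Union of all anchor-to-target shortest paths."""

    anchor: str
    nodes: frozenset
    edges: frozenset
    targets_reached: frozenset
    targets_unreachable: frozenset

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def roles(self) -> dict:
        out = {}
        for n in self.nodes:
            if n == self.anchor:
                out[n] = "anchor"
            elif n in self.targets_reached:
                out[n] = "target"
            else:
                out[n] = "intermediate"
        return out


def shortest_path_subnetwork(
    network: nx.DiGraph, anchor: str, targets: set
) -> Subnetwork:
    """All tied shortest directed paths from anchor to each target.

    The subnetwork is the union of the nodes and edges of every
    shortest path; targets not reachable from the anchor are listed in
    ``targets_unreachable``.
    """
    if anchor not in network:
        raise KeyError(f"anchor {anchor!r} not in network")
    targets = set(targets) & set(network.nodes)
    nodes = {anchor}
    edges = set()
    reached, unreachable = set(), set()
    lengths = nx.single_source_shortest_path_length(network, anchor)
    for t in sorted(targets):
        if t == anchor:
            continue
        if t not in lengths:
            unreachable.add(t)
            continue
        reached.add(t)
        for path in nx.all_shortest_paths(network, anchor, t):
            nodes.update(path)
            edges.update(zip(path[:-1], path[1:]))
    return Subnetwork(
        anchor=anchor,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        targets_reached=frozenset(reached),
        targets_unreachable=frozenset(unreachable),
    )


def downstream_neighborhood(network: nx.DiGraph, node: str, k: int) -> set:
    """Nodes at directed distance 1..k from ``node`` (source excluded)."""
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    if k < 1:
        raise ValueError("k must be >= 1")
    lengths = nx.single_source_shortest_path_length(network, node, cutoff=k)
    return {n for n, d in lengths.items() if 1 <= d <= k}


def layer_enrichment_profile(
    network: nx.DiGraph,
    node: str,
    signature: set,
    k_max: int,
    universe: set | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of each k-layer neighborhood for a signature.

    ``universe`` defaults to the network's node set. Layers with an
    empty neighborhood (or an empty signature restriction) are recorded
    as non-informative rows (p = NaN) rather than errors.
    """
    universe = set(universe) if universe is not None else set(network.nodes)
    signature = set(signature) & universe
    rows = []
    for k in range(1, k_max + 1):
        hood = downstream_neighborhood(network, node, k) & universe
        if not hood or not signature:
            rows.append(
                {"layer": k, "n_neighborhood": len(hood), "overlap": 0,
                 "p": float("nan"), "fold_enrichment": float("nan")}
            )
            continue
        res = fisher_enrichment(hood, signature, universe)
        rows.append(
            {
                "layer": k,
                "n_neighborhood": len(hood),
                "overlap": res["overlap"],
                "p": res["p"],
                "fold_enrichment": res["fold_enrichment"],
            }
        )
    return pd.DataFrame(rows).set_index("layer")


def key_driver_analysis(
    network: nx.DiGraph,
    target_set: set,
    h: int = 6,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Rank nodes by enrichment of their h-layer downstream neighborhood.

    Every node with a non-empty downstream neighborhood is tested by a
    one-sided Fisher exact test for over-representation of
    ``target_set`` in its neighborhood, with the network's node set as
    the universe; BH adjustment across tested nodes. Drivers satisfy
    fdr < fdr_cutoff; the table is sorted by p ascending, then by
    neighborhood size descending, then node id.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    universe = set(network.nodes)
    target_set = set(target_set) & universe
    if not target_set:
        raise ValueError("target set does not intersect the network")
    rows = []
    for node in sorted(network.nodes):
        hood = downstream_neighborhood(network, node, h)
        if not hood:
            continue  # leaf: nothing downstream to test
        res = fisher_enrichment(hood, target_set, universe)
        rows.append(
            {
                "node": node,
                "layer": h,
                "neighborhood_size": len(hood),
                "overlap": res["overlap"],
                "p": res["p"],
                "fold_enrichment": res["fold_enrichment"],
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["node", "layer", "neighborhood_size", "overlap", "p",
                     "fold_enrichment", "fdr", "is_driver"]
        ).set_index("node")
    out = pd.DataFrame(rows).set_index("node")
    out["fdr"] = bh_adjust(out["p"])
    out["is_driver"] = out["fdr"] < fdr_cutoff
    out = out.reset_index()
    out = out.sort_values(
        by=["p", "neighborhood_size", "node"], ascending=[True, False, True]
    )
    return out.set_index("node")
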