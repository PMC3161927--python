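"""Known/putative interaction networks and Cytoscape-compatible export.

A :class:`Network` is a labelled undirected multigraph over
:class:`~orthowalk.model.GeneID` nodes.  Each edge carries a ``kind``
("known" for experimental records, "putative" for projected pairs) plus
free attributes (ipx, pcs, provenance).  Parallel known/putative edges
between the same pair are deliberately retained: the union network
never collapses duplicate edges across kinds.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Iterable

import networkx as nx

from .model import GeneID, GenePair, MitabInteraction, unordered_pair

logger = logging.getLogger(__name__)

KNOWN = "known"
PUTATIVE = "putative"


class Network:
    """Thin domain wrapper around an undirected ``networkx.MultiGraph``."""

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiGraph()

    # -- construction ------------------------------------------------------
    def add_node(self, gene: GeneID, **attrs: Any) -> None:
        self.graph.add_node(gene, **attrs)

    def add_edge(self, a: GeneID, b: GeneID, kind: str, **attrs: Any) -> None:
        self.graph.add_edge(a, b, kind=kind, **attrs)

    def copy(self) -> "Network":
        return Network(self.graph.copy())

    # -- queries -----------------------------------------------------------
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def n_unique_pairs(self) -> int:
        return len({unordered_pair(a, b) for a, b in self.graph.edges()})

    def has_edge(self, a: GeneID, b: GeneID) -> bool:
        return self.graph.has_edge(a, b)

    def neighbors(self, gene: GeneID) -> set[GeneID]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def nodes(self) -> list[GeneID]:
        return list(self.graph.nodes())

    def edges(self) -> list[tuple[GeneID, GeneID, dict]]:
        return [(a, b, dict(d)) for a, b, d in self.graph.edges(data=True)]

    def induced_subgraph(self, genes: set[GeneID]) -> "Network":
        return Network(self.graph.subgraph(genes).copy())


def build_network(edges: Iterable[tuple[GeneID, GeneID, dict]],
                  kind: str) -> Network:
    """Build a single-kind network from (gene_a, gene_b, attrs) triples.

    For ``kind="putative"`` duplicate unordered pairs collapse to one
    edge (first attributes win); for ``kind="known"`` every record is
    its own edge.
    """
    net = Network()
    seen: set[GenePair] = set()
    for a, b, attrs in edges:
        if kind == PUTATIVE:
            pair = unordered_pair(a, b)
            if pair in seen:
                continue
            seen.add(pair)
        net.add_edge(a, b, kind=kind, **attrs)
    return net


def known_network(interactions: Iterable[MitabInteraction]) -> Network:
    """The known network: one edge per experimental interaction record."""
    return build_network(
        ((r.interactor_a, r.interactor_b,
          {"provenance": r.interaction_ac,
           "detection_method": r.detection_method,
           "interaction_type": r.interaction_type})
         for r in interactions),
        kind=KNOWN,
    )


def putative_network(scored: Iterable[tuple]) -> Network:
    """The putative network from ``score_putative_set`` output: one edge
    per unique pair, annotated with ipx, tier and pcs."""
    return build_network(
        ((p.gene_a, p.gene_b,
          {"ipx": res.ipx, "tier": res.tier.value, "pcs": pcs,
           "provenance": f"n_evidence={len(p.evidence)}"})
         for p, res, pcs in scored),
        kind=PUTATIVE,
    )


def union_networks(known: Network, putative: Network) -> Network:
    """Union of node sets; concatenation of edge multisets.

    Duplicate edges across kinds are kept parallel, so the union's edge
    count is exactly the sum of the two inputs'.
    """
    g = nx.MultiGraph()
    for net in (known, putative):
        g.add_nodes_from(net.graph.nodes(data=True))
        for a, b, data in net.graph.edges(data=True):
            g.add_edge(a, b, **data)
    return Network(g)


def neighborhood(net: Network, seeds: set[GeneID], depth: int = 1) -> Network:
    """Induced subgraph on the seeds and their nearest neighbours.

    Seeds absent from the network are ignored with a warning.
    """
    if depth != 1:
        raise ValueError("only depth-1 (nearest-neighbour) extraction is supported")
    present = set()
    for s in seeds:
        if s in net.graph:
            present.add(s)
        else:
            logger.warning("seed %s absent from network; ignored", s)
    keep = set(present)
    for s in present:
        keep |= net.neighbors(s)
    sub = net.induced_subgraph(keep)
    for s in present:
        sub.graph.nodes[s]["is_input"] = True
    return sub


def threshold_subnetwork(net: Network, ipx_min: float) -> Network:
    """Drop putative edges with IPX below ``ipx_min``.

    Known edges are untouched.  Nodes orphaned by the removal (degree 0
    and not flagged ``is_input``) are dropped.  Monotone: raising the
    threshold never adds edges.
    """
    g = net.graph.copy()
    to_drop = [
        (a, b, key) for a, b, key, data in g.edges(keys=True, data=True)
        if data.get("kind") == PUTATIVE and data.get("ipx", float("-inf")) < ipx_min
    ]
    g.remove_edges_from(to_drop)
    orphans = [
        n for n in g.nodes()
        if g.degree(n) == 0 and not g.nodes[n].get("is_input", False)
    ]
    g.remove_nodes_from(orphans)
    return Network(g)


def _round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def network_stats(net: Network, input_gene_count: int | None = None) -> dict:
    """Summary statistics: node/edge/pair counts, component sizes, and
    the surviving-ID percentage relative to the input gene count
    (printed with one decimal, half-up)."""
    comp_sizes = sorted(
        (len(c) for c in nx.connected_components(net.graph)), reverse=True)
    stats = {
        "nodes": net.n_nodes(),
        "edges": net.n_edges(),
        "unique_pairs": net.n_unique_pairs(),
        "n_components": len(comp_sizes),
        "component_sizes": comp_sizes,
    }
    if input_gene_count is not None:
        if input_gene_count > 0:
            stats["surviving_pct"] = _round_half_up(
                100.0 * net.n_nodes() / input_gene_count, 1)
        else:
            stats["surviving_pct"] = 0.0
    return stats


# --------------------------------------------------------------------------
# Cytoscape-compatible export (SIF + attribute TSVs)
# --------------------------------------------------------------------------

_EDGE_ATTR_COLUMNS = ("ipx", "pcs", "kind", "provenance")
_NODE_ATTR_COLUMNS = ("is_input",)


def export_cytoscape(net: Network, basepath: str | Path) -> list[Path]:
    """Write ``<base>.sif``, ``<base>.edges.tsv`` and ``<base>.nodes.tsv``.

    SIF lines are ``geneA <kind> geneB``; parallel edges produce one
    line each.  The attribute TSVs carry enough to re-import the network
    losslessly via :func:`import_cytoscape`.
    """
    base = Path(basepath)
    sif = base.with_suffix(".sif")
    edges_tsv = base.parent / (base.name + ".edges.tsv")
    nodes_tsv = base.parent / (base.name + ".nodes.tsv")

    edge_rows = sorted(
        ((str(a), str(b), data) for a, b, data in net.edges()),
        key=lambda row: (row[0], row[1], row[2].get("kind", ""),
                         str(row[2].get("provenance", ""))),
    )
    with open(sif, "w", encoding="utf-8") as fh:
        for a, b, data in edge_rows:
            fh.write(f"{a}\t{data.get('kind', KNOWN)}\t{b}\n")
    with open(edges_tsv, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\t" + "\t".join(_EDGE_ATTR_COLUMNS) + "\n")
        for a, b, data in edge_rows:
            cells = [a, b] + [
                "-" if data.get(c) is None else repr(data[c])
                if isinstance(data.get(c), float) else str(data.get(c, "-"))
                for c in _EDGE_ATTR_COLUMNS
            ]
            fh.write("\t".join(cells) + "\n")
    with open(nodes_tsv, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(_NODE_ATTR_COLUMNS) + "\n")
        for node in sorted(net.nodes()):
            attrs = net.graph.nodes[node]
            fh.write("\t".join(
                [str(node)] + [str(attrs.get(c, False)) for c in _NODE_ATTR_COLUMNS]
            ) + "\n")
    return [sif, edges_tsv, nodes_tsv]


def _parse_node(token: str) -> GeneID:
    ns, acc = token.split(":", 1)
    return GeneID(ns, acc)


def import_cytoscape(basepath: str | Path) -> Network:
    """Rebuild a network from the export of :func:`export_cytoscape`."""
    base = Path(basepath)
    net = Network()
    nodes_tsv = base.parent / (base.name + ".nodes.tsv")
    edges_tsv = base.parent / (base.name + ".edges.tsv")
    with open(nodes_tsv, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            net.add_node(_parse_node(cells["gene"]),
                         is_input=cells.get("is_input") == "True")
    with open(edges_tsv, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            attrs: dict[str, Any] = {}
            for col in ("ipx", "pcs"):
                if cells.get(col, "-") != "-":
                    attrs[col] = float(cells[col])
            if cells.get("provenance", "-") != "-":
                attrs["provenance"] = cells["provenance"]
            net.add_edge(_parse_node(cells["gene_a"]),
                         _parse_node(cells["gene_b"]),
                         kind=cells.get("kind", KNOWN), **attrs)
    return net
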