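"""Rule-based JAK/STAT subnetwork extraction.

Genes responsive to treatment are selected from one arm/week slice of
the PD-effect table by two rules — the n most significantly changed
genes, and genes that interact with JAK1 or JAK2 via transcriptional
regulation or phosphorylation with adjusted p below a threshold — then
joined with the anchor set {STAT1, STAT2, JAK1, JAK2, TYK2} and
connected through a user-supplied interaction table.  Components not
containing an anchor are removed before export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .types import ValidationError

log = logging.getLogger("slepd")

DEFAULT_ANCHORS = ("STAT1", "STAT2", "JAK1", "JAK2", "TYK2")
QUALIFYING_MECHANISMS = ("transcription_regulation", "phosphorylation")
JAK_HUBS = ("JAK1", "JAK2")
NODE_CATEGORIES = ("kinase", "ligand_receptor", "transcription_factor", "other")


@dataclass
class GeneNetwork:
    """An anchored interaction subnetwork ready for export."""

    graph: nx.Graph
    anchors: tuple
    no_edges: bool = False

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def node_table(self) -> pd.DataFrame:
        rows = [
            dict(gene=n, category=d.get("category", "other"),
                 provenance=d.get("provenance", ""))
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene", "category", "provenance"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            dict(source=u, target=v, mechanism=d.get("mechanism", "other"))
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "mechanism"])


def _clean_edges(edges: pd.DataFrame) -> pd.DataFrame:
    need = {"source", "mechanism", "target"}
    if not need <= set(edges.columns):
        raise ValidationError(f"edge table needs columns {sorted(need)}")
    edges = edges.copy()
    loops = edges["source"] == edges["target"]
    if loops.any():
        log.info("dropping %d self-loop edge(s)", int(loops.sum()))
        edges = edges[~loops]
    # canonical order for determinism regardless of file row order
    return edges.sort_values(["source", "target", "mechanism"]).reset_index(drop=True)


def select_network_genes(
    pd_effects: pd.DataFrame,
    edges: pd.DataFrame,
    anchors=DEFAULT_ANCHORS,
    n_top: int = 50,
    alpha: float = 0.05,
    directed: bool = False,
) -> pd.DataFrame:
    """Select treatment-responsive genes with per-gene provenance.

    ``pd_effects`` must already be restricted to one arm and week and
    contain columns feature_id, p, q.  Selection is the union of
    (a) the ``n_top`` smallest-q genes ('top50'), (b) genes sharing a
    transcription-regulation or phosphorylation edge with JAK1 or JAK2
    and q < alpha ('jak_interactor'), and (c) the anchors.  With
    ``directed=False`` (default) an edge qualifies in either direction.
    """
    if pd_effects.empty:
        raise ValidationError("pd_effects is empty")
    if pd_effects["feature_id"].duplicated().any():
        raise ValidationError(
            "pd_effects must be one arm/week slice (duplicate feature ids)"
        )
    edges = _clean_edges(edges)
    ranked = pd_effects.dropna(subset=["q"]).sort_values(
        ["q", "p", "feature_id"], kind="stable"
    )
    top = set(ranked["feature_id"].head(n_top))

    qual = edges[edges["mechanism"].isin(QUALIFYING_MECHANISMS)]
    partners = set()
    for hub in JAK_HUBS:
        partners |= set(qual.loc[qual["source"] == hub, "target"])
        if not directed:
            partners |= set(qual.loc[qual["target"] == hub, "source"])
    significant = set(ranked.loc[ranked["q"] < alpha, "feature_id"])
    interactors = (partners & significant) - set(JAK_HUBS)

    provenance = {}
    for g in top:
        provenance.setdefault(g, set()).add("top50")
    for g in interactors:
        provenance.setdefault(g, set()).add("jak_interactor")
    for g in anchors:
        provenance.setdefault(g, set()).add("anchor")
    rows = [
        dict(gene=g, provenance=",".join(sorted(tags)))
        for g, tags in sorted(provenance.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "provenance"])


def build_connected_subnetwork(
    selected: pd.DataFrame,
    edges: pd.DataFrame,
    anchors=DEFAULT_ANCHORS,
    annotations: dict | None = None,
) -> GeneNetwork:
    """Induce the selected genes' subgraph and keep anchored components.

    Nodes in connected components that contain no anchor are removed.
    ``annotations`` maps gene → category (kinase / ligand_receptor /
    transcription_factor); unannotated genes become 'other'.  An empty
    edge table yields the anchors as isolated nodes, flagged
    ``no_edges``.
    """
    annotations = annotations or {}
    prov = dict(zip(selected["gene"], selected["provenance"]))
    genes = set(prov) | set(anchors)

    def _annotate(graph):
        for n in graph.nodes:
            cat = annotations.get(n, "other")
            if cat not in NODE_CATEGORIES:
                raise ValidationError(f"unknown node category {cat!r} for {n}")
            graph.nodes[n]["category"] = cat
            graph.nodes[n]["provenance"] = prov.get(n, "anchor")

    edges = _clean_edges(edges)
    if edges.empty:
        log.warning("empty edge table: returning anchors only")
        graph = nx.Graph()
        graph.add_nodes_from(anchors)
        _annotate(graph)
        return GeneNetwork(graph=graph, anchors=tuple(anchors), no_edges=True)

    universe = set(edges["source"]) | set(edges["target"])
    if not universe & set(anchors):
        raise ValidationError("no anchor gene present in the edge table")

    graph = nx.Graph()
    graph.add_nodes_from(sorted(genes))
    for row in edges.itertuples(index=False):
        if row.source in genes and row.target in genes:
            graph.add_edge(row.source, row.target, mechanism=row.mechanism)
    keep = set()
    for component in nx.connected_components(graph):
        if component & set(anchors):
            keep |= component
    graph = graph.subgraph(keep).copy()
    _annotate(graph)
    return GeneNetwork(graph=graph, anchors=tuple(anchors))


def write_network(network: GeneNetwork, prefix) -> None:
    """Export GraphML plus node/edge TSVs under a path prefix."""
    nx.write_graphml(network.graph, f"{prefix}.graphml")
    network.node_table().to_csv(f"{prefix}_nodes.tsv", sep="\t", index=False)
    network.edge_table().to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)
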