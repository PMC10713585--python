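"""KGML pathway parsing and directed target mining.

Each KGML file becomes a directed graph: nodes are ``<entry>`` elements
(gene entries mapped to symbol sets via a KEGG-id map, compounds kept
as traversable intermediates), edges run from the ``entry1`` to the
``entry2`` attribute of each ``<relation>``. Group entries are expanded:
every edge touching a group is replicated to each component.

Target mining asks, for each ligand-receptor pair and each latent
feature, whether the feature lies downstream of the pair (a directed
path from a receptor-subunit node — or from the ligand node when no
receptor subunit is in the pathway — to the feature) or upstream of it
(a directed path from the feature to that anchor). Paths must have
length >= 1; relation subtypes are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from lxml import etree

from .containers import LRPair

logger = logging.getLogger(__name__)

DOWNSTREAM = "downstream"
UPSTREAM = "upstream"


@dataclass
class PathwayGraph:
    """A parsed KGML pathway as a directed entry graph."""

    pathway_id: str
    graph: nx.DiGraph
    symbol_nodes: dict[str, set[int]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def symbols(self) -> set[str]:
        return set(self.symbol_nodes)


@dataclass(frozen=True)
class TargetHit:
    """A latent feature positioned relative to a ligand-receptor pair."""

    pathway_id: str
    ligand: str
    receptor: str
    feature: str
    position: str

    def as_row(self) -> tuple[str, str, str, str, str]:
        return (self.pathway_id, self.ligand, self.receptor, self.feature,
                self.position)


def parse_kgml(source, symbol_map: dict[str, str]) -> PathwayGraph:
    """Parse one KGML document into a :class:`PathwayGraph`.

    ``source`` is a path or file-like object. Gene entries whose KEGG
    ids are absent from ``symbol_map`` are retained with an empty
    symbol set (with a warning); relations referencing unknown entries
    are skipped with a warning.
    """
    tree = etree.parse(source)
    root = tree.getroot()
    pathway_name = root.get("name", "")
    pathway_id = pathway_name.split(":")[-1] if pathway_name else ""

    graph = nx.DiGraph()
    groups: dict[int, list[int]] = {}
    for entry in root.findall("entry"):
        entry_id = int(entry.get("id"))
        entry_type = entry.get("type", "")
        kegg_ids = tuple(entry.get("name", "").split())
        if entry_type == "group":
            groups[entry_id] = [
                int(c.get("id")) for c in entry.findall("component")
            ]
            continue
        symbols: set[str] = set()
        if entry_type == "gene":
            for kegg_id in kegg_ids:
                symbol = symbol_map.get(kegg_id)
                if symbol is None:
                    logger.warning(
                        "%s: no symbol for KEGG id %s", pathway_id, kegg_id
                    )
                else:
                    symbols.add(symbol)
        graph.add_node(
            entry_id,
            kegg_ids=kegg_ids,
            symbols=frozenset(symbols),
            entry_type=entry_type,
        )

    def expand(entry_id: int) -> list[int]:
        return groups.get(entry_id, [entry_id])

    for relation in root.findall("relation"):
        entry1 = int(relation.get("entry1"))
        entry2 = int(relation.get("entry2"))
        subtypes = tuple(s.get("name", "") for s in relation.findall("subtype"))
        for source_id in expand(entry1):
            for target_id in expand(entry2):
                if source_id not in graph or target_id not in graph:
                    logger.warning(
                        "%s: relation %s->%s references a missing entry; skipped",
                        pathway_id, entry1, entry2,
                    )
                    continue
                graph.add_edge(source_id, target_id, subtypes=subtypes)

    symbol_nodes: dict[str, set[int]] = {}
    for node, data in graph.nodes(data=True):
        for symbol in data["symbols"]:
            symbol_nodes.setdefault(symbol, set()).add(node)
    logger.info(
        "%s: %d nodes, %d edges", pathway_id,
        graph.number_of_nodes(), graph.number_of_edges(),
    )
    return PathwayGraph(pathway_id, graph, symbol_nodes)


def _reachable(graph: nx.DiGraph, sources: set[int]) -> set[int]:
    """Nodes reachable from any source along >= 1 edge."""
    out: set[int] = set()
    for source in sources:
        out |= nx.descendants(graph, source)
    return out


def find_targets(
    graphs: list[PathwayGraph],
    pairs: list[LRPair],
    features,
) -> list[TargetHit]:
    """Position latent features relative to ligand-receptor pairs.

    For each pathway and pair, the search anchors on every receptor
    subunit present in that pathway; if none is present the ligand node
    anchors instead (and the hit reports the full receptor complex).
    A downstream hit is a feature reachable from the anchor, an
    upstream hit a feature that reaches the anchor. One hit is emitted
    per (pathway, ligand, receptor, feature, position); a feature that
    is itself a pair member never yields a self-hit.
    """
    if not pairs:
        raise ValueError("no ligand-receptor pairs supplied")
    features = set(features)
    hits: set[TargetHit] = set()
    for pathway in graphs:
        present = pathway.symbol_nodes
        feature_nodes = {
            f: present[f] for f in features if f in present
        }
        if not feature_nodes:
            continue
        for pair in pairs:
            receptor_subunits_in = [
                s for s in pair.receptor_subunits if s in present
            ]
            if receptor_subunits_in:
                anchors = [(s, present[s]) for s in receptor_subunits_in]
            else:
                ligand_nodes = {
                    n for s in pair.ligand_subunits for n in present.get(s, ())
                }
                if not ligand_nodes:
                    continue
                anchors = [(pair.receptor_label, ligand_nodes)]
            pair_members = set(pair.ligand_subunits) | set(pair.receptor_subunits)
            for receptor_label, anchor_nodes in anchors:
                down = _reachable(pathway.graph, anchor_nodes)
                up_sources = {
                    f: nodes for f, nodes in feature_nodes.items()
                }
                for feature, nodes in up_sources.items():
                    if feature in pair_members:
                        continue
                    if nodes & down:
                        hits.add(
                            TargetHit(pathway.pathway_id, pair.ligand_label,
                                      receptor_label, feature, DOWNSTREAM)
                        )
                    if _reachable(pathway.graph, nodes) & anchor_nodes:
                        hits.add(
                            TargetHit(pathway.pathway_id, pair.ligand_label,
                                      receptor_label, feature, UPSTREAM)
                        )
    return sorted(hits, key=lambda h: h.as_row())


def hits_table(hits: list[TargetHit]) -> "pd.DataFrame":  # noqa: F821
    """TSV-ready (Pathway, Ligand, Receptor, Feature, Position) rows."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "Pathway": h.pathway_id,
                "Ligand": h.ligand,
                "Receptor": h.receptor,
                "Feature": h.feature,
                "Position": h.position,
            }
            for h in hits
        ]
    )
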