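"""Typed heterogeneous knowledge-graph store.

A :class:`KnowledgeGraph` holds typed nodes (Disease, Compound, Gene,
ontology terms, ...) and undirected typed edges loaded from flat TSV
tables.  Traversal is relation-type-agnostic: relation types are kept as
per-edge annotations for filtering and provenance, but two nodes are
adjacent if *any* relation links them.  Parallel edges between the same
unordered pair with the same relation type are collapsed; distinct
relation types accumulate on the single stored edge.  Self-loops are
dropped at load time (no metapath used downstream traverses them).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["source_id", "source_type", "relation_type", "target_id", "target_type"]
NODE_COLUMNS = ["node_id", "node_type", "display_name"]


class GraphConsistencyError(ValueError):
    """A node was declared with conflicting types, or an endpoint is missing."""


class GraphLookupError(KeyError):
    """A node id was requested that does not exist in the graph."""


class KnowledgeGraph:
    """Undirected heterogeneous graph with typed nodes and typed edges.

    Thin wrapper around :class:`networkx.Graph`; node type lives in the
    ``node_type`` node attribute, the set of relation types linking a
    pair in the ``relations`` edge attribute.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, node_type: str, display_name: str = "") -> None:
        existing = self._g.nodes.get(node_id)
        if existing is not None and existing["node_type"] != node_type:
            raise GraphConsistencyError(
                f"node {node_id!r} declared with conflicting types "
                f"{existing['node_type']!r} and {node_type!r}"
            )
        if existing is None:
            self._g.add_node(node_id, node_type=node_type, display_name=display_name)
        elif display_name and not existing.get("display_name"):
            self._g.nodes[node_id]["display_name"] = display_name

    def add_edge(self, source_id: str, target_id: str, relation_type: str) -> None:
        for nid in (source_id, target_id):
            if nid not in self._g:
                raise GraphConsistencyError(
                    f"edge endpoint {nid!r} is not a declared node"
                )
        if source_id == target_id:
            raise GraphConsistencyError(f"self-loop on node {source_id!r}")
        data = self._g.get_edge_data(source_id, target_id)
        if data is None:
            self._g.add_edge(source_id, target_id, relations={relation_type})
        else:
            data["relations"].add(relation_type)

    # -- basic accessors ----------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Number of simple undirected pairs (parallel relations collapse)."""
        return self._g.number_of_edges()

    def node_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    def node_type(self, node_id: str) -> str:
        self._require(node_id)
        return self._g.nodes[node_id]["node_type"]

    def display_name(self, node_id: str) -> str:
        self._require(node_id)
        return self._g.nodes[node_id].get("display_name", "")

    def has_node(self, node_id: str) -> bool:
        return node_id in self._g

    def node_types(self) -> set[str]:
        return {d["node_type"] for _, d in self._g.nodes(data=True)}

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True) if d["node_type"] == node_type
        )

    def degree(self, node_id: str) -> int:
        self._require(node_id)
        return self._g.degree(node_id)

    def edge_tuples(self) -> set[tuple[str, str, str]]:
        """All (min_id, max_id, relation_type) triples, one per relation."""
        out = set()
        for u, v, d in self._g.edges(data=True):
            a, b = sorted((u, v))
            for rel in d["relations"]:
                out.add((a, b, rel))
        return out

    def node_tuples(self) -> set[tuple[str, str]]:
        return {(n, d["node_type"]) for n, d in self._g.nodes(data=True)}

    def _require(self, node_id: str) -> None:
        if node_id not in self._g:
            raise GraphLookupError(f"unknown node id {node_id!r}")

    # -- traversal -----------------------------------------------------

    def neighbors(self, node_id: str, neighbor_type: str | None = None) -> list[str]:
        """Adjacent nodes, optionally restricted to one node type.

        Adjacency ignores relation types (any relation makes two nodes
        neighbors).  Returned sorted lexicographically for determinism.
        """
        self._require(node_id)
        nbrs = self._g.neighbors(node_id)
        if neighbor_type is None:
            return sorted(nbrs)
        return sorted(
            n for n in nbrs if self._g.nodes[n]["node_type"] == neighbor_type
        )

    # -- filtering -----------------------------------------------------

    def subset(
        self,
        keep_node_types: Iterable[str],
        keep_relation_types: Iterable[str] | None = None,
    ) -> "KnowledgeGraph":
        """Induced subgraph on the kept node types (and relation types).

        An edge survives iff both endpoints survive and, when a relation
        filter is given, at least one of its relation types is kept (the
        stored relation set is then restricted to the kept ones).  The
        original graph is not modified.
        """
        keep_nt = set(keep_node_types)
        if not keep_nt:
            raise ValueError("keep_node_types must be non-empty")
        keep_rt = None if keep_relation_types is None else set(keep_relation_types)
        if keep_nt.isdisjoint(self.node_types()):
            logger.warning(
                "node-type filter %s matches no node in the graph; "
                "returning an empty graph",
                sorted(keep_nt),
            )
        out = KnowledgeGraph()
        for n, d in self._g.nodes(data=True):
            if d["node_type"] in keep_nt:
                out._g.add_node(n, **dict(d))
        for u, v, d in self._g.edges(data=True):
            if u in out._g and v in out._g:
                rels = d["relations"] if keep_rt is None else d["relations"] & keep_rt
                if rels:
                    out._g.add_edge(u, v, relations=set(rels))
        logger.info(
            "subset: kept %d/%d nodes, %d/%d edges",
            out.n_nodes, self.n_nodes, out.n_edges, self.n_edges,
        )
        return out


# -- operations (module-level surface) --------------------------------


def subset_graph(
    kg: KnowledgeGraph,
    keep_node_types: Iterable[str],
    keep_relation_types: Iterable[str] | None = None,
) -> KnowledgeGraph:
    return kg.subset(keep_node_types, keep_relation_types)


def neighbors(kg: KnowledgeGraph, node_id: str, neighbor_type: str) -> list[str]:
    return kg.neighbors(node_id, neighbor_type)


def load_graph(edge_table: str | Path, node_table: str | Path | None = None) -> KnowledgeGraph:
    """Load a typed edge-list TSV (plus optional node TSV) into a graph.

    The edge TSV must carry the columns ``source_id, source_type,
    relation_type, target_id, target_type``; the node TSV (isolated
    nodes, display names) carries ``node_id, node_type[, display_name]``.
    Duplicate parallel edges collapse to one per unordered pair and
    relation type; self-loops are dropped with a logged count.
    """
    kg = KnowledgeGraph()
    if node_table is not None:
        ndf = pd.read_csv(node_table, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in NODE_COLUMNS[:2] if c not in ndf.columns]
        if missing:
            raise ValueError(f"node table missing columns: {missing}")
        for row in ndf.itertuples(index=True):
            if not row.node_id or not row.node_type:
                raise ValueError(
                    f"node table line {row.Index + 2}: empty node_id or node_type"
                )
            kg.add_node(row.node_id, row.node_type, getattr(row, "display_name", ""))

    edf = pd.read_csv(edge_table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in edf.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    n_self = 0
    for row in edf.itertuples(index=True):
        line = row.Index + 2  # header is line 1
        if not all([row.source_id, row.source_type, row.relation_type,
                    row.target_id, row.target_type]):
            raise ValueError(f"edge table line {line}: empty required field")
        try:
            kg.add_node(row.source_id, row.source_type)
            kg.add_node(row.target_id, row.target_type)
        except GraphConsistencyError as exc:
            raise GraphConsistencyError(f"edge table line {line}: {exc}") from exc
        if row.source_id == row.target_id:
            n_self += 1
            continue
        kg.add_edge(row.source_id, row.target_id, row.relation_type)
    if n_self:
        logger.info("dropped %d self-loop edge rows", n_self)
    logger.info("loaded graph: %d nodes, %d edges", kg.n_nodes, kg.n_edges)
    return kg


def save_graph(kg: KnowledgeGraph, edge_table: str | Path, node_table: str | Path) -> None:
    """Write the graph back to the TSV dialect accepted by :func:`load_graph`."""
    erows = []
    for a, b, rel in sorted(kg.edge_tuples()):
        erows.append((a, kg.node_type(a), rel, b, kg.node_type(b)))
    pd.DataFrame(erows, columns=EDGE_COLUMNS).to_csv(edge_table, sep="\t", index=False)
    nrows = [(n, kg.node_type(n), kg.display_name(n)) for n in kg.node_ids()]
    pd.DataFrame(nrows, columns=NODE_COLUMNS).to_csv(node_table, sep="\t", index=False)
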