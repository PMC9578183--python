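"""Typed reference graph: the database behind distant-supervision labeling.

The graph is a pure membership index over typed nodes and typed edges
(metaedges).  Four metaedges are modeled first-class — DaG, CtD, CbG, GiG —
and anything else loads as ``other`` and is ignored downstream.  GiG edges
are undirected and stored with lexicographically ordered endpoints.

Two sources are supported: a Hetionet-style JSON (nodes carry
``identifier``/``kind``, edges carry ``source_id``/``target_id``/``kind``)
and a plain TSV dialect for toy graphs (2-column lines declare nodes,
3-column lines declare edges).
"""

from __future__ import annotations

import json
import logging
from typing import Iterable

from .corpus import EDGE_TYPE_SIGNATURES
from .errors import GraphLoadError

logger = logging.getLogger(__name__)

#: Hetionet relationship names mapped onto in-scope metaedge abbreviations,
#: keyed by (source kind, edge kind, target kind).
_HETIONET_KINDS = {
    ("Disease", "associates", "Gene"): "DaG",
    ("Compound", "treats", "Disease"): "CtD",
    ("Compound", "binds", "Gene"): "CbG",
    ("Gene", "interacts", "Gene"): "GiG",
}


class ReferenceGraph:
    """Typed nodes plus typed edges, queryable by exact pair membership."""

    def __init__(self):
        self._nodes: dict[str, str] = {}
        self._edges: set[tuple[str, str, str]] = set()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, node_type: str) -> None:
        self._nodes[node_id] = node_type

    def add_edge(self, source_id: str, target_id: str, metaedge: str) -> None:
        for endpoint in (source_id, target_id):
            if endpoint not in self._nodes:
                raise GraphLoadError(
                    f"edge ({source_id}, {target_id}, {metaedge}) references "
                    f"undeclared node {endpoint!r}"
                )
        if metaedge in EDGE_TYPE_SIGNATURES:
            want = EDGE_TYPE_SIGNATURES[metaedge]
            got = (self._nodes[source_id], self._nodes[target_id])
            if got != want:
                raise GraphLoadError(
                    f"edge ({source_id}, {target_id}) endpoint types {got} do "
                    f"not match the {metaedge} signature {want}"
                )
        self._edges.add(self._canonical(source_id, target_id, metaedge))

    @staticmethod
    def _canonical(source_id, target_id, metaedge):
        if metaedge == "GiG" and target_id < source_id:
            source_id, target_id = target_id, source_id
        return (source_id, target_id, metaedge)

    # -- queries ----------------------------------------------------------
    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node_type(self, node_id: str) -> str:
        return self._nodes[node_id]

    def has_edge(self, pair: tuple[str, str], metaedge: str) -> bool:
        """Exact edge membership; symmetric in the pair for GiG."""
        return self._canonical(pair[0], pair[1], metaedge) in self._edges

    def edges_of(self, metaedge: str) -> list[tuple[str, str]]:
        return sorted((s, t) for s, t, m in self._edges if m == metaedge)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self._nodes.items() if t == node_type)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(cls, lines: Iterable[str] | str) -> "ReferenceGraph":
        """Load the toy TSV dialect.

        2 columns → node ``(id, type)``; 3 columns → edge
        ``(source, target, metaedge)``.  Unknown metaedge labels map to
        ``other``; edges referencing undeclared nodes are a load error.
        """
        if isinstance(lines, str):
            lines = lines.splitlines()
        graph = cls()
        edges = []
        for line in lines:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                graph.add_node(fields[0], fields[1])
            elif len(fields) == 3:
                edges.append(tuple(fields))
            else:
                raise GraphLoadError(
                    f"expected 2 (node) or 3 (edge) columns, got {len(fields)}: "
                    f"{line!r}"
                )
        for source, target, metaedge in edges:
            if metaedge not in EDGE_TYPE_SIGNATURES:
                metaedge = "other"
            graph.add_edge(source, target, metaedge)
        return graph

    @classmethod
    def from_tsv_path(cls, path) -> "ReferenceGraph":
        with open(path) as fh:
            return cls.from_tsv(fh)

    def to_tsv(self) -> str:
        out = []
        for node_id in sorted(self._nodes):
            out.append(f"{node_id}\t{self._nodes[node_id]}")
        for source, target, metaedge in sorted(self._edges):
            out.append(f"{source}\t{target}\t{metaedge}")
        return "\n".join(out) + "\n"

    @classmethod
    def from_hetionet_json(cls, source) -> "ReferenceGraph":
        """Load a Hetionet-style JSON object, dict, path or file handle.

        Edge ``kind`` may already be a metaedge abbreviation or a Hetionet
        relationship name (``associates``, ``treats``, ``binds``,
        ``interacts``); anything unrecognized maps to ``other``.  Node and
        edge counts are logged after the load.
        """
        if isinstance(source, dict):
            payload = source
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        elif hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)

        graph = cls()
        for node in payload.get("nodes", []):
            graph.add_node(str(node["identifier"]), str(node["kind"]))
        for edge in payload.get("edges", []):
            source_id = _endpoint_id(edge["source_id"])
            target_id = _endpoint_id(edge["target_id"])
            kind = str(edge.get("kind", "other"))
            if kind not in EDGE_TYPE_SIGNATURES:
                try:
                    key = (graph.node_type(source_id), kind,
                           graph.node_type(target_id))
                except KeyError:
                    raise GraphLoadError(
                        f"edge ({source_id}, {target_id}, {kind}) references "
                        "an undeclared node"
                    ) from None
                kind = _HETIONET_KINDS.get(key, "other")
            graph.add_edge(source_id, target_id, kind)
        logger.info(
            "loaded reference graph: %d nodes, %d edges",
            graph.n_nodes, graph.n_edges,
        )
        return graph


def load_reference_graph(source) -> ReferenceGraph:
    """Dispatch on source shape: ``.json`` → Hetionet JSON, else toy TSV."""
    text = None
    if isinstance(source, str) and "\n" not in source and "\t" not in source:
        path = source
        if path.endswith(".json"):
            return ReferenceGraph.from_hetionet_json(path)
        return ReferenceGraph.from_tsv_path(path)
    if isinstance(source, (dict,)):
        return ReferenceGraph.from_hetionet_json(source)
    text = source
    if isinstance(text, str) and text.lstrip().startswith("{"):
        return ReferenceGraph.from_hetionet_json(text)
    return ReferenceGraph.from_tsv(text)


def _endpoint_id(value) -> str:
    # Hetionet JSON encodes endpoints as ["Kind", identifier]; toy files may
    # use a plain identifier.
    if isinstance(value, (list, tuple)):
        return str(value[-1])
    return str(value)
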