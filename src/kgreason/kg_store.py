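"""Typed property-graph store with category subsumption and TSV/Cypher I/O.

Nodes are identified by CURIEs (``PREFIX:LOCALID``) and carry one or more
category tokens from a miniature upper-level ontology (a forest rooted at
a universal ``named_thing`` category, standing in for a full biomedical
type system). Edges are directed subject→object assertions carrying a
primary knowledge source and an optional list of curated publication
identifiers; parallel edges between the same endpoints are permitted and
kept distinct, because the same assertion may be contributed by several
curated sources. Degree and downstream matching treat edges as
undirected: answer paths such as chemical–gene–disease are traversed
without regard to assertion direction.

File formats:

* nodes TSV, header ``id  name  category`` — category is a
  pipe-separated list of tokens, most specific first;
* edges TSV, header ``subject  predicate  object  primary_source
  publications`` — publications is a pipe-separated list of PMIDs,
  possibly empty;
* a write-only Cypher text export (one ``CREATE``/``MATCH..CREATE``
  statement per line) for loading into a Cypher-speaking store.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Curie",
    "NodeRecord",
    "EdgeRecord",
    "TypeOntology",
    "KnowledgeGraph",
    "GraphLoadError",
    "default_ontology",
    "load_graph",
    "write_graph",
    "export_cypher",
]


class GraphLoadError(ValueError):
    """Raised when a graph file is malformed or internally inconsistent."""


@dataclass(frozen=True, order=True)
class Curie:
    """Compact Uniform Resource Identifier, serialized ``PREFIX:LOCALID``.

    The prefix is uppercase-normalized on parse so identifiers join
    stably across files; the local id is kept verbatim.
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or not self.local_id:
            raise ValueError(f"CURIE needs non-empty prefix and local id: {self!r}")
        if ":" in self.prefix or ":" in self.local_id:
            raise ValueError(f"CURIE parts must not contain ':': {self!r}")

    @classmethod
    def parse(cls, text: str) -> "Curie":
        parts = text.split(":")
        if len(parts) != 2:
            raise ValueError(f"CURIE must have exactly one ':' separator: {text!r}")
        return cls(prefix=parts[0].upper(), local_id=parts[1])

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"


@dataclass(frozen=True)
class NodeRecord:
    id: Curie
    name: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"node {self.id} has no categories")


@dataclass(frozen=True)
class EdgeRecord:
    subject: Curie
    predicate: str
    object: Curie
    primary_source: str
    curated_publications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"self-loop edge on {self.subject}")
        if len(set(self.curated_publications)) != len(self.curated_publications):
            raise ValueError(
                f"duplicate publications on edge {self.subject}-{self.object}"
            )

    def key(self) -> tuple:
        return (
            str(self.subject),
            self.predicate,
            str(self.object),
            self.primary_source,
        )


ROOT_CATEGORY = "named_thing"


@dataclass(frozen=True)
class TypeOntology:
    """A category forest: every category reaches a universal root."""

    categories: frozenset[str]
    parent: Mapping[str, str]

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if child not in self.categories or par not in self.categories:
                raise ValueError(f"parent link {child}->{par} uses unknown category")
        roots = self.categories - set(self.parent)
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, got {sorted(roots)}")
        # cycle / reachability check
        for cat in self.categories:
            seen = set()
            cur = cat
            while cur in self.parent:
                if cur in seen:
                    raise ValueError(f"cycle in ontology at {cur}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def root(self) -> str:
        (r,) = self.categories - set(self.parent)
        return r

    def ancestors(self, category: str) -> list[str]:
        """Category plus its parent chain up to the root, inclusive."""
        if category not in self.categories:
            raise KeyError(f"unknown category: {category!r}")
        chain = [category]
        while chain[-1] in self.parent:
            chain.append(self.parent[chain[-1]])
        return chain

    def is_subtype(self, child: str, ancestor: str) -> bool:
        """True iff *ancestor* lies on *child*'s parent chain (reflexive)."""
        if ancestor not in self.categories:
            raise KeyError(f"unknown category: {ancestor!r}")
        return ancestor in self.ancestors(child)


def default_ontology() -> TypeOntology:
    """The miniature category forest shipped with the package.

    ``named_thing`` subsumes chemical_substance, gene, disease and
    phenotypic_feature — the four entity types the worked examples and
    generated graphs use.
    """
    cats = {
        ROOT_CATEGORY,
        "chemical_substance",
        "gene",
        "disease",
        "phenotypic_feature",
    }
    parent = {c: ROOT_CATEGORY for c in cats - {ROOT_CATEGORY}}
    return TypeOntology(categories=frozenset(cats), parent=parent)


@dataclass
class KnowledgeGraph:
    nodes: dict[Curie, NodeRecord]
    edges: list[EdgeRecord]
    ontology: TypeOntology = field(default_factory=default_ontology)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for curie, node in self.nodes.items():
            if curie != node.id:
                raise GraphLoadError(f"node keyed {curie} holds record for {node.id}")
            for cat in node.categories:
                if cat not in self.ontology.categories:
                    raise GraphLoadError(f"node {curie}: unknown category {cat!r}")
        for edge in self.edges:
            for endpoint in (edge.subject, edge.object):
                if endpoint not in self.nodes:
                    raise GraphLoadError(
                        f"edge {edge.subject}-[{edge.predicate}]->{edge.object} "
                        f"references absent node {endpoint}"
                    )

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degree(self, node: Curie) -> int:
        """Number of incident edges, direction ignored."""
        if node not in self.nodes:
            raise KeyError(f"unknown node: {node}")
        return sum(1 for e in self.edges if node in (e.subject, e.object))

    def max_degree(self) -> int:
        if not self.nodes:
            return 0
        counts: dict[Curie, int] = {c: 0 for c in self.nodes}
        for e in self.edges:
            counts[e.subject] += 1
            counts[e.object] += 1
        return max(counts.values())

    def edges_between(self, a: Curie, b: Curie) -> list[EdgeRecord]:
        """All edges joining a and b in either direction."""
        return [e for e in self.edges if {e.subject, e.object} == {a, b}]


# ---------------------------------------------------------------------------
# TSV I/O

_NODE_HEADER = ["id", "name", "category"]
_EDGE_HEADER = ["subject", "predicate", "object", "primary_source", "publications"]


def _read_tsv(path: Path, expected_header: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != list(expected_header):
            raise GraphLoadError(
                f"{path}: header {reader.fieldnames} != expected {list(expected_header)}"
            )
        return list(reader)


def load_graph(
    nodes_table: str | Path,
    edges_table: str | Path,
    ontology: TypeOntology | None = None,
) -> KnowledgeGraph:
    """Load a knowledge graph from nodes/edges TSV files.

    Malformed rows are rejected with an error naming the offending row;
    nothing is skipped silently.
    """
    ontology = ontology or default_ontology()
    nodes: dict[Curie, NodeRecord] = {}
    for i, row in enumerate(_read_tsv(Path(nodes_table), _NODE_HEADER), start=2):
        try:
            curie = Curie.parse(row["id"])
            cats = frozenset(t for t in row["category"].split("|") if t)
            record = NodeRecord(id=curie, name=row["name"], categories=cats)
        except (ValueError, KeyError, TypeError) as exc:
            raise GraphLoadError(f"{nodes_table} row {i}: {exc}") from exc
        if curie in nodes:
            raise GraphLoadError(f"{nodes_table} row {i}: duplicate node id {curie}")
        for cat in record.categories:
            if cat not in ontology.categories:
                raise GraphLoadError(
                    f"{nodes_table} row {i}: unknown category {cat!r}"
                )
        nodes[curie] = record

    edges: list[EdgeRecord] = []
    for i, row in enumerate(_read_tsv(Path(edges_table), _EDGE_HEADER), start=2):
        try:
            pubs = tuple(p for p in (row["publications"] or "").split("|") if p)
            edge = EdgeRecord(
                subject=Curie.parse(row["subject"]),
                predicate=row["predicate"],
                object=Curie.parse(row["object"]),
                primary_source=row["primary_source"],
                curated_publications=pubs,
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise GraphLoadError(f"{edges_table} row {i}: {exc}") from exc
        for endpoint in (edge.subject, edge.object):
            if endpoint not in nodes:
                raise GraphLoadError(
                    f"{edges_table} row {i}: edge references absent node {endpoint}"
                )
        edges.append(edge)

    return KnowledgeGraph(nodes=nodes, edges=edges, ontology=ontology)


def write_graph(
    kg: KnowledgeGraph, nodes_table: str | Path, edges_table: str | Path
) -> None:
    """Write canonicalized (sorted-row) TSV files; inverse of load_graph."""
    with open(nodes_table, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_NODE_HEADER)
        for curie in sorted(kg.nodes, key=str):
            node = kg.nodes[curie]
            # most specific first: non-root categories before the root
            cats = sorted(node.categories, key=lambda c: (c == kg.ontology.root, c))
            w.writerow([str(curie), node.name, "|".join(cats)])
    with open(edges_table, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_EDGE_HEADER)
        for e in sorted(kg.edges, key=lambda e: e.key()):
            w.writerow(
                [
                    str(e.subject),
                    e.predicate,
                    str(e.object),
                    e.primary_source,
                    "|".join(e.curated_publications),
                ]
            )


# ---------------------------------------------------------------------------
# Cypher export

def _cypher_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("'", "\\'")


def export_cypher(kg: KnowledgeGraph) -> str:
    """Deterministic Cypher CREATE script reproducing the graph.

    Nodes are emitted first (sorted by CURIE) as ``CREATE`` statements
    labelled with their categories, then edges (sorted by subject,
    predicate, object) as ``MATCH .. CREATE`` statements keyed on node
    ids. The export is write-only: the package ships no Cypher parser.
    """
    lines: list[str] = []
    for curie in sorted(kg.nodes, key=str):
        node = kg.nodes[curie]
        labels = "".join(f":`{c}`" for c in sorted(node.categories))
        lines.append(
            f"CREATE ({labels} {{id: '{_cypher_escape(str(curie))}', "
            f"name: '{_cypher_escape(node.name)}'}})"
        )
    for e in sorted(kg.edges, key=lambda e: e.key()):
        pubs = ", ".join(f"'{_cypher_escape(p)}'" for p in e.curated_publications)
        lines.append(
            f"MATCH (a {{id: '{_cypher_escape(str(e.subject))}'}}), "
            f"(b {{id: '{_cypher_escape(str(e.object))}'}}) "
            f"CREATE (a)-[:`{e.predicate}` "
            f"{{primary_source: '{_cypher_escape(e.primary_source)}', "
            f"publications: [{pubs}]}}]->(b)"
        )
    return "\n".join(lines) + ("\n" if lines else "")
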