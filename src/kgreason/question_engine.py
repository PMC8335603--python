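"""Question graphs (meta-graphs) and exhaustive answer-subgraph matching.

A question graph is a small template: each question node (QNode) is
either *pinned* to a concrete CURIE or constrained to a category from
the graph's ontology; each question edge (QEdge) optionally constrains
the predicate. An answer is an injective assignment of graph nodes to
question nodes such that every question edge is witnessed by at least
one graph edge between the bound endpoints, direction ignored. Parallel
witnessing edges strengthen a single answer rather than multiplying it
into several; they are collected into that answer's edge bindings.

Matching is a backtracking search ordered most-constrained-qnode-first,
which is exhaustive (complete and sound against brute-force enumeration)
and perfectly adequate at desk scale — no indexes, no query planner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import yaml

from kgreason.kg_store import Curie, EdgeRecord, KnowledgeGraph

__all__ = [
    "QNode",
    "QEdge",
    "QuestionGraph",
    "AnswerSubgraph",
    "QuestionParseError",
    "parse_question",
    "format_question",
    "match_question",
]


class QuestionParseError(ValueError):
    """Raised for structurally invalid question documents."""


@dataclass(frozen=True)
class QNode:
    """A question node: pinned to a CURIE, constrained to a category, or both."""

    qid: str
    binding: Curie | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.binding is None and self.category is None:
            raise QuestionParseError(
                f"qnode {self.qid!r} needs a curie binding or a category"
            )


@dataclass(frozen=True)
class QEdge:
    qeid: str
    source_qid: str
    target_qid: str
    predicate: str | None = None

    def __post_init__(self) -> None:
        if self.source_qid == self.target_qid:
            raise QuestionParseError(f"qedge {self.qeid!r} is a self-loop")


@dataclass(frozen=True)
class QuestionGraph:
    qnodes: tuple[QNode, ...]
    qedges: tuple[QEdge, ...]

    def __post_init__(self) -> None:
        qids = [q.qid for q in self.qnodes]
        if len(set(qids)) != len(qids):
            raise QuestionParseError("duplicate qids")
        qeids = [e.qeid for e in self.qedges]
        if len(set(qeids)) != len(qeids):
            raise QuestionParseError("duplicate qeids")
        known = set(qids)
        for e in self.qedges:
            for qid in (e.source_qid, e.target_qid):
                if qid not in known:
                    raise QuestionParseError(
                        f"qedge {e.qeid!r} references unknown qnode {qid!r}"
                    )
        if not self.qnodes:
            raise QuestionParseError("question has no qnodes")
        if not self._connected():
            raise QuestionParseError("question graph is not connected")

    def _connected(self) -> bool:
        adj: dict[str, set[str]] = {q.qid: set() for q in self.qnodes}
        for e in self.qedges:
            adj[e.source_qid].add(e.target_qid)
            adj[e.target_qid].add(e.source_qid)
        stack = [self.qnodes[0].qid]
        seen: set[str] = set()
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(adj[cur] - seen)
        return len(seen) == len(self.qnodes)

    def qnode(self, qid: str) -> QNode:
        for q in self.qnodes:
            if q.qid == qid:
                return q
        raise KeyError(qid)


@dataclass(frozen=True)
class AnswerSubgraph:
    """Node and edge bindings of one match.

    ``node_bindings`` maps qid → bound CURIE (injectively);
    ``edge_bindings`` maps qeid → the tuple of all graph edges witnessing
    that question edge between the bound endpoints.
    """

    node_bindings: Mapping[str, Curie]
    edge_bindings: Mapping[str, tuple[EdgeRecord, ...]]

    def sort_key(self) -> tuple:
        return tuple(sorted((qid, str(c)) for qid, c in self.node_bindings.items()))


# ---------------------------------------------------------------------------
# Parsing (YAML, which is a superset of JSON)

def parse_question(doc: str) -> QuestionGraph:
    """Parse a question document.

    Format::

        nodes:
          - {qid: n0, curie: "FIX:CO"}
          - {qid: n1, category: gene}
          - {qid: n2, curie: "FIX:MS"}
        edges:
          - {qeid: e0, source: n0, target: n1}
          - {qeid: e1, source: n1, target: n2, predicate: related_to}
    """
    try:
        data = yaml.safe_load(doc)
    except yaml.YAMLError as exc:
        raise QuestionParseError(f"unparseable question document: {exc}") from exc
    if not isinstance(data, dict) or "nodes" not in data:
        raise QuestionParseError("question document must be a mapping with 'nodes'")
    qnodes = []
    for spec in data["nodes"]:
        curie = spec.get("curie")
        qnodes.append(
            QNode(
                qid=str(spec["qid"]),
                binding=Curie.parse(curie) if curie else None,
                category=spec.get("category"),
            )
        )
    qedges = []
    for spec in data.get("edges") or []:
        qedges.append(
            QEdge(
                qeid=str(spec["qeid"]),
                source_qid=str(spec["source"]),
                target_qid=str(spec["target"]),
                predicate=spec.get("predicate"),
            )
        )
    return QuestionGraph(qnodes=tuple(qnodes), qedges=tuple(qedges))


def format_question(qg: QuestionGraph) -> str:
    """Serialize a question graph back to its YAML document form."""
    nodes = []
    for q in qg.qnodes:
        spec: dict = {"qid": q.qid}
        if q.binding is not None:
            spec["curie"] = str(q.binding)
        if q.category is not None:
            spec["category"] = q.category
        nodes.append(spec)
    edges = []
    for e in qg.qedges:
        spec = {"qeid": e.qeid, "source": e.source_qid, "target": e.target_qid}
        if e.predicate is not None:
            spec["predicate"] = e.predicate
        edges.append(spec)
    return yaml.safe_dump({"nodes": nodes, "edges": edges}, sort_keys=False)


# ---------------------------------------------------------------------------
# Matching

def _candidates(kg: KnowledgeGraph, qnode: QNode) -> list[Curie]:
    if qnode.binding is not None:
        if qnode.binding not in kg.nodes:
            return []
        node = kg.nodes[qnode.binding]
        if qnode.category is not None and not any(
            kg.ontology.is_subtype(c, qnode.category) for c in node.categories
        ):
            return []
        return [qnode.binding]
    return sorted(
        (
            c
            for c, node in kg.nodes.items()
            if any(kg.ontology.is_subtype(cat, qnode.category) for cat in node.categories)
        ),
        key=str,
    )


def _witnesses(
    kg: KnowledgeGraph, a: Curie, b: Curie, predicate: str | None
) -> tuple[EdgeRecord, ...]:
    hits = [
        e
        for e in kg.edges_between(a, b)
        if predicate is None or e.predicate == predicate
    ]
    return tuple(sorted(hits, key=lambda e: e.key()))


def match_question(kg: KnowledgeGraph, qg: QuestionGraph) -> list[AnswerSubgraph]:
    """Enumerate all answer subgraphs for a question against a graph.

    Pinned qnodes must bind their CURIE (a pin absent from the graph
    yields zero answers, not an error); category-constrained qnodes bind
    any node carrying a subtype of the constraint; distinct qnodes bind
    distinct graph nodes; each qedge needs at least one witnessing edge
    in either direction (exact predicate match when constrained). The
    result is sorted lexicographically on the node bindings, so repeated
    calls return identical ordered output.
    """
    cands = {q.qid: _candidates(kg, q) for q in qg.qnodes}
    # most-constrained first: fewest candidates, ties by qid
    order = sorted(cands, key=lambda qid: (len(cands[qid]), qid))
    answers: list[AnswerSubgraph] = []
    bound: dict[str, Curie] = {}
    used: set[Curie] = set()

    def extend(depth: int) -> None:
        if depth == len(order):
            edge_bindings: dict[str, tuple[EdgeRecord, ...]] = {}
            for qe in qg.qedges:
                w = _witnesses(
                    kg, bound[qe.source_qid], bound[qe.target_qid], qe.predicate
                )
                if not w:
                    return
                edge_bindings[qe.qeid] = w
            answers.append(
                AnswerSubgraph(node_bindings=dict(bound), edge_bindings=edge_bindings)
            )
            return
        qid = order[depth]
        for curie in cands[qid]:
            if curie in used:
                continue
            # prune: every qedge whose endpoints are both bound must be witnessed
            bound[qid] = curie
            ok = all(
                _witnesses(kg, bound[qe.source_qid], bound[qe.target_qid], qe.predicate)
                for qe in qg.qedges
                if qe.source_qid in bound and qe.target_qid in bound
            )
            if ok:
                used.add(curie)
                extend(depth + 1)
                used.discard(curie)
            del bound[qid]

    extend(0)
    answers.sort(key=lambda a: a.sort_key())
    return answers
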