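"""Answer-subgraph scoring: literature-weighted resistance + informativeness.

Each question edge of an answer gets a *support* value pooling its
evidence: curated publications (counted once across parallel witness
edges) at full weight, abstract co-occurrence counts at a discounted
weight, reflecting that curated assertions carry more weight than raw
literature co-occurrence. Support S maps to an edge weight

    w = (S + eps) / (S + eps + k),   0 < w < 1,

a saturating form whose reciprocal r = 1/w is treated as an electrical
resistance. The answer's *confidence* is 1 / (1 + R_eff), where R_eff is
the two-terminal effective resistance of the answer subgraph between its
pinned terminals (series resistances add along a path; parallel evidence
branches lower the resistance, so more independent paths mean higher
confidence). An *informativeness* score rewards answers routed through
low-degree (specific) nodes over hub-like generic ones, and the final
score is a confidence-dominant weighted geometric mean of the two.

All constants live in :class:`RankingParams` and may be overridden from
a YAML config.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from kgreason.kg_store import Curie, EdgeRecord, KnowledgeGraph
from kgreason.omnicorp_lite import CooccurrenceIndex
from kgreason.question_engine import AnswerSubgraph, QuestionGraph

__all__ = [
    "RankingParams",
    "EdgeSupport",
    "ScoredAnswer",
    "edge_support",
    "answer_resistance",
    "confidence_score",
    "informativeness_score",
    "rank_answers",
]


@dataclass(frozen=True)
class RankingParams:
    """Tunable constants of the scoring model.

    curated_pub_weight
        Contribution of one curated publication to edge support.
    omnicorp_pub_weight
        Contribution of one co-occurring abstract; must not exceed the
        curated weight, so curated evidence always dominates.
    saturation_k
        Half-saturation constant of the support→weight map: an edge with
        support k has weight ≈ 0.5.
    support_floor_eps
        Small positive floor keeping weights strictly positive (hence
        resistances finite) on evidence-free edges; doubles as the
        informativeness floor in the combined score.
    combine_gamma
        Exponent of confidence in the geometric-mean combination;
        1 - gamma goes to informativeness.
    """

    curated_pub_weight: float = 1.0
    omnicorp_pub_weight: float = 0.25
    saturation_k: float = 10.0
    support_floor_eps: float = 0.01
    combine_gamma: float = 0.8

    def __post_init__(self) -> None:
        if self.curated_pub_weight <= 0:
            raise ValueError("curated_pub_weight must be positive")
        if not (0 < self.omnicorp_pub_weight <= self.curated_pub_weight):
            raise ValueError(
                "omnicorp_pub_weight must be in (0, curated_pub_weight]"
            )
        if self.saturation_k <= 0 or self.support_floor_eps <= 0:
            raise ValueError("saturation_k and support_floor_eps must be positive")
        if not (0 <= self.combine_gamma <= 1):
            raise ValueError("combine_gamma must be in [0, 1]")

    @classmethod
    def from_mapping(cls, data: Mapping[str, float]) -> "RankingParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ranking parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class EdgeSupport:
    curated_count: int
    omnicorp_count: int
    support: float
    weight: float
    resistance: float


def edge_support(
    witnesses: Sequence[EdgeRecord],
    index: CooccurrenceIndex | None,
    params: RankingParams = RankingParams(),
) -> EdgeSupport:
    """Pool evidence for one question edge across its parallel witnesses.

    Curated publications are unioned over the witness edges (the same
    PMID asserted by two sources counts once); the co-occurrence count
    comes from the literature index for the common endpoint pair.
    """
    if not witnesses:
        raise ValueError("edge_support needs at least one witness edge")
    endpoint_sets = {frozenset((e.subject, e.object)) for e in witnesses}
    if len(endpoint_sets) != 1:
        raise ValueError("witness edges must share endpoints")
    curated: set[str] = set()
    for e in witnesses:
        curated.update(e.curated_publications)
    a, b = witnesses[0].subject, witnesses[0].object
    omnicorp = index.cooccurrence_count(a, b) if index is not None else 0
    support = (
        params.curated_pub_weight * len(curated)
        + params.omnicorp_pub_weight * omnicorp
    )
    weight = (support + params.support_floor_eps) / (
        support + params.support_floor_eps + params.saturation_k
    )
    return EdgeSupport(
        curated_count=len(curated),
        omnicorp_count=omnicorp,
        support=support,
        weight=weight,
        resistance=1.0 / weight,
    )


# ---------------------------------------------------------------------------
# Effective resistance

def _effective_resistance_matrix(
    nodes: Sequence[str], branches: Iterable[tuple[str, str, float]]
) -> np.ndarray:
    """Pairwise effective resistances via the Laplacian pseudoinverse.

    Branch resistances become conductances on the weighted Laplacian L;
    R_eff(s, t) = (e_s - e_t)^T L^+ (e_s - e_t). Parallel branches
    between the same pair simply add their conductances.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    L = np.zeros((n, n))
    for a, b, resistance in branches:
        if resistance <= 0:
            raise ValueError("branch resistance must be positive")
        g = 1.0 / resistance
        i, j = idx[a], idx[b]
        L[i, i] += g
        L[j, j] += g
        L[i, j] -= g
        L[j, i] -= g
    Lp = np.linalg.pinv(L)
    d = np.diag(Lp)
    return d[:, None] + d[None, :] - 2 * Lp


def answer_resistance(
    answer: AnswerSubgraph,
    qg: QuestionGraph,
    supports: Mapping[str, EdgeSupport],
) -> float:
    """Two-terminal effective resistance of an answer subgraph.

    Each question edge contributes one branch with its support-derived
    resistance. Terminals are the two pinned qnodes when the question
    pins exactly two; otherwise the mean pairwise effective resistance
    over all pinned qnode pairs (or over all qnode pairs when fewer than
    two are pinned). For a simple path this is the series sum of the
    branch resistances.
    """
    qids = [q.qid for q in qg.qnodes]
    branches = [
        (qe.source_qid, qe.target_qid, supports[qe.qeid].resistance)
        for qe in qg.qedges
    ]
    if len(qids) == 1:
        return 0.0
    R = _effective_resistance_matrix(qids, branches)
    idx = {q: i for i, q in enumerate(qids)}
    # connectivity check: a disconnected answer has no finite two-terminal
    # resistance; detect via the component structure of the branches
    comp = {q: q for q in qids}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for a, b, _ in branches:
        comp[find(a)] = find(b)
    if len({find(q) for q in qids}) > 1:
        raise ValueError("answer subgraph is disconnected")

    pinned = [q.qid for q in qg.qnodes if q.binding is not None]
    if len(pinned) == 2:
        s, t = pinned
        return float(R[idx[s], idx[t]])
    pool = pinned if len(pinned) >= 2 else qids
    pairs = list(itertools.combinations(pool, 2))
    return float(np.mean([R[idx[a], idx[b]] for a, b in pairs]))


def confidence_score(resistance: float) -> float:
    """Map effective resistance onto (0, 1): 1 / (1 + R), decreasing in R."""
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    return 1.0 / (1.0 + resistance)


def informativeness_score(answer: AnswerSubgraph, kg: KnowledgeGraph) -> float:
    """Degree-based specificity of an answer in [0, 1].

    Mean over the answer's question edges of

        1 - (log d(s) + log d(o)) / (2 log Dmax),

    where d is the endpoint's degree in the full graph and Dmax the
    graph's maximum degree (clamped to at least 2). Answers routed
    through low-degree, specific nodes score near 1; answers through
    hub nodes score near 0.
    """
    dmax = max(kg.max_degree(), 2)
    log_dmax = math.log(dmax)
    bound_degree: dict[str, int] = {}
    for qid, curie in answer.node_bindings.items():
        if curie not in kg.nodes:
            raise KeyError(f"bound node {curie} absent from graph")
        bound_degree[qid] = kg.degree(curie)
    terms = []
    for qeid, witnesses in answer.edge_bindings.items():
        s, o = witnesses[0].subject, witnesses[0].object
        spec = 1.0 - (math.log(kg.degree(s)) + math.log(kg.degree(o))) / (2 * log_dmax)
        terms.append(min(1.0, max(0.0, spec)))
    if not terms:
        # single-node answer: specificity of the lone binding
        (qid,) = answer.node_bindings
        d = bound_degree[qid]
        return min(1.0, max(0.0, 1.0 - math.log(max(d, 1)) / log_dmax))
    return float(np.mean(terms))


@dataclass(frozen=True)
class ScoredAnswer:
    answer: AnswerSubgraph
    supports: Mapping[str, EdgeSupport]
    resistance: float
    confidence: float
    informativeness: float
    score: float


def _combine(confidence: float, informativeness: float, params: RankingParams) -> float:
    g = params.combine_gamma
    inf = informativeness if informativeness > 0 else params.support_floor_eps
    return confidence**g * inf ** (1 - g)


def rank_answers(
    answers: Sequence[AnswerSubgraph],
    qg: QuestionGraph,
    kg: KnowledgeGraph,
    index: CooccurrenceIndex | None,
    params: RankingParams = RankingParams(),
) -> list[ScoredAnswer]:
    """Score every answer and sort by score descending.

    Ties break lexicographically on the sorted node-binding CURIEs, so
    the ranking is deterministic and invariant under permutation of the
    input list.
    """
    scored = []
    for answer in answers:
        supports = {
            qeid: edge_support(witnesses, index, params)
            for qeid, witnesses in answer.edge_bindings.items()
        }
        resistance = answer_resistance(answer, qg, supports)
        # a single-node answer has zero resistance: perfect confidence
        confidence = confidence_score(resistance) if resistance > 0 else 1.0
        informativeness = informativeness_score(answer, kg)
        scored.append(
            ScoredAnswer(
                answer=answer,
                supports=supports,
                resistance=resistance,
                confidence=confidence,
                informativeness=informativeness,
                score=_combine(confidence, informativeness, params),
            )
        )
    scored.sort(key=lambda s: (-s.score, s.answer.sort_key()))
    return scored


def report_ranked(scored: Sequence[ScoredAnswer]) -> str:
    """Human-readable ranked-answer report (one block per answer)."""
    lines = []
    for rank, s in enumerate(scored, start=1):
        bindings = ", ".join(
            f"{qid}={curie}" for qid, curie in sorted(s.answer.node_bindings.items())
        )
        lines.append(f"#{rank} score={s.score:.4f} [{bindings}]")
        lines.append(
            f"    resistance={s.resistance:.4f} confidence={s.confidence:.4f} "
            f"informativeness={s.informativeness:.4f}"
        )
        for qeid in sorted(s.supports):
            sup = s.supports[qeid]
            lines.append(
                f"    {qeid}: curated={sup.curated_count} "
                f"cooccurrence={sup.omnicorp_count} weight={sup.weight:.4f}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
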