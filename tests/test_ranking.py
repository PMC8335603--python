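import itertools

import numpy as np
import pytest

from kgreason.fixtures import FixtureSpec, make_example_fixture
from kgreason.kg_store import Curie, EdgeRecord, KnowledgeGraph, NodeRecord
from kgreason.omnicorp_lite import CooccurrenceIndex
from kgreason.question_engine import (
    AnswerSubgraph,
    QEdge,
    QNode,
    QuestionGraph,
    match_question,
)
from kgreason.ranking import (
    EdgeSupport,
    RankingParams,
    answer_resistance,
    confidence_score,
    edge_support,
    informativeness_score,
    rank_answers,
)

PARAMS = RankingParams()


def C(s):
    return Curie.parse(s)


def make_edge(s, o, source="CTD", pubs=()):
    return EdgeRecord(
        subject=C(s), predicate="related_to", object=C(o),
        primary_source=source, curated_publications=tuple(pubs),
    )


class TestEdgeSupport:
    def test_no_evidence_floor(self):
        sup = edge_support([make_edge("FIX:A", "FIX:B")], None, PARAMS)
        assert sup.support == 0
        assert sup.weight == pytest.approx(0.01 / 10.01, rel=1e-12)
        assert sup.resistance == pytest.approx(10.01 / 0.01, rel=1e-12)

    def test_curated_plus_cooccurrence(self):
        index = CooccurrenceIndex()
        index.set_pair_count(C("FIX:A"), C("FIX:B"), 4)
        sup = edge_support(
            [make_edge("FIX:A", "FIX:B", pubs=("PMID:1", "PMID:2"))], index, PARAMS
        )
        assert sup.curated_count == 2 and sup.omnicorp_count == 4
        assert sup.support == pytest.approx(3.0)
        assert sup.weight == pytest.approx(3.01 / 13.01, rel=1e-12)

    def test_parallel_witnesses_union_publications(self):
        edges = [
            make_edge("FIX:A", "FIX:B", "HETIO", ("PMID:1", "PMID:2")),
            make_edge("FIX:A", "FIX:B", "PHAROS", ("PMID:2", "PMID:3")),
        ]
        sup = edge_support(edges, None, PARAMS)
        assert sup.curated_count == 3  # PMID:2 counted once

    def test_weight_monotone_resistance_antitone(self):
        def weight(cur, omni):
            index = CooccurrenceIndex()
            index.set_pair_count(C("FIX:A"), C("FIX:B"), omni)
            pubs = tuple(f"PMID:{i}" for i in range(cur))
            return edge_support([make_edge("FIX:A", "FIX:B", pubs=pubs)], index, PARAMS)

        for cur, omni in itertools.product(range(4), range(4)):
            base = weight(cur, omni)
            assert weight(cur + 1, omni).weight > base.weight
            assert weight(cur, omni + 1).weight > base.weight
            assert weight(cur + 1, omni).resistance < base.resistance

    def test_curated_dominates_cooccurrence(self):
        def w(cur, omni):
            index = CooccurrenceIndex()
            index.set_pair_count(C("FIX:A"), C("FIX:B"), omni)
            pubs = tuple(f"PMID:{i}" for i in range(cur))
            return edge_support(
                [make_edge("FIX:A", "FIX:B", pubs=pubs)], index, PARAMS
            ).weight

        for cur, omni in itertools.product(range(5), range(5)):
            assert w(cur + 1, omni) >= w(cur, omni + 1)


# --- effective resistance -------------------------------------------------

def sup(resistance):
    return EdgeSupport(0, 0, 0.0, 1.0 / resistance, resistance)


def circuit_question(qeids_and_pairs):
    """Question graph with pinned terminals s, t and typed intermediates."""
    qids = {q for _, a, b in qeids_and_pairs for q in (a, b)}
    qnodes = []
    for q in sorted(qids):
        if q == "s":
            qnodes.append(QNode(qid="s", binding=C("FIX:S")))
        elif q == "t":
            qnodes.append(QNode(qid="t", binding=C("FIX:T")))
        else:
            qnodes.append(QNode(qid=q, category="gene"))
    qedges = tuple(
        QEdge(qeid=qeid, source_qid=a, target_qid=b) for qeid, a, b in qeids_and_pairs
    )
    return QuestionGraph(qnodes=tuple(qnodes), qedges=qedges)


def dummy_answer(qg):
    bindings = {q.qid: C(f"FIX:{q.qid.upper()}") for q in qg.qnodes}
    return AnswerSubgraph(node_bindings=bindings, edge_bindings={})


def random_series_parallel(rng, depth=0):
    """(edge list builder, closed-form resistance) for a random circuit.

    Returns (pairs, R) where pairs is a list of (a, b, resistance)
    between fresh node names, with terminals 's' and 't'.
    """
    counter = itertools.count()

    def build(a, b, d):
        if d >= 3 or rng.random() < 0.4:
            r = float(rng.uniform(0.5, 5.0))
            return [(a, b, r)], r
        if rng.random() < 0.5:  # series
            mid = f"m{next(counter)}"
            left, r1 = build(a, mid, d + 1)
            right, r2 = build(mid, b, d + 1)
            return left + right, r1 + r2
        # parallel
        p1, r1 = build(a, b, d + 1)
        p2, r2 = build(a, b, d + 1)
        return p1 + p2, r1 * r2 / (r1 + r2)

    return build("s", "t", depth)


def resistance_of(pairs):
    qeids = [(f"e{i}", a, b) for i, (a, b, _) in enumerate(pairs)]
    qg = circuit_question(qeids)
    supports = {f"e{i}": sup(r) for i, (_, _, r) in enumerate(pairs)}
    return answer_resistance(dummy_answer(qg), qg, supports)


class TestAnswerResistance:
    def test_series_path(self):
        pairs = [("s", "m", 2.0), ("m", "t", 3.0)]
        assert resistance_of(pairs) == pytest.approx(5.0, abs=1e-9)

    def test_parallel_branches(self):
        pairs = [("s", "t", 2.0), ("s", "t", 2.0)]
        assert resistance_of(pairs) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_series_parallel_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        pairs, expected = random_series_parallel(rng)
        node_count = len({q for a, b, _ in pairs for q in (a, b)})
        if node_count > 6:
            pairs, expected = [("s", "t", 1.5)], 1.5
        assert resistance_of(pairs) == pytest.approx(expected, abs=1e-9)

    def test_mean_pairwise_when_not_two_pins(self):
        # triangle of equal resistors, no pinned qnodes: every pair has
        # R_eff = 2/3, so the mean is 2/3 as well
        qg = QuestionGraph(
            qnodes=tuple(QNode(qid=q, category="gene") for q in "abc"),
            qedges=(
                QEdge(qeid="e0", source_qid="a", target_qid="b"),
                QEdge(qeid="e1", source_qid="b", target_qid="c"),
                QEdge(qeid="e2", source_qid="a", target_qid="c"),
            ),
        )
        supports = {q: sup(1.0) for q in ("e0", "e1", "e2")}
        assert answer_resistance(dummy_answer(qg), qg, supports) == pytest.approx(
            2.0 / 3.0, abs=1e-9
        )


class TestConfidence:
    def test_fixed_point(self):
        assert confidence_score(1.0) == pytest.approx(0.5)

    def test_limits(self):
        assert confidence_score(1e-9) == pytest.approx(1.0, abs=1e-6)
        assert confidence_score(1e9) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_parallel_branch_never_lowers_confidence(self, seed):
        rng = np.random.default_rng(seed)
        pairs, _ = random_series_parallel(rng)
        if len({q for a, b, _ in pairs for q in (a, b)}) > 6:
            pairs = [("s", "m", 1.0), ("m", "t", 2.0)]
        base = confidence_score(resistance_of(pairs))
        augmented = confidence_score(
            resistance_of(pairs + [("s", "t", float(rng.uniform(0.5, 5.0)))])
        )
        assert augmented >= base - 1e-12


def tiny_kg(edge_pairs, categories=None):
    nodes = {}
    for a, b in edge_pairs:
        for local in (a, b):
            curie = C(f"FIX:{local}")
            nodes.setdefault(
                curie,
                NodeRecord(
                    id=curie, name=local,
                    categories=frozenset({(categories or {}).get(local, "gene")}),
                ),
            )
    edges = [make_edge(f"FIX:{a}", f"FIX:{b}") for a, b in edge_pairs]
    return KnowledgeGraph(nodes=nodes, edges=edges)


class TestInformativeness:
    def answer_for(self, kg, qid_to_local, qeid_to_pair):
        return AnswerSubgraph(
            node_bindings={q: C(f"FIX:{l}") for q, l in qid_to_local.items()},
            edge_bindings={
                qeid: tuple(
                    e for e in kg.edges
                    if {e.subject, e.object} == {C(f"FIX:{a}"), C(f"FIX:{b}")}
                )
                for qeid, (a, b) in qeid_to_pair.items()
            },
        )

    def test_all_degree_one_is_one(self):
        kg = tiny_kg([("A", "B")])
        ans = self.answer_for(kg, {"x": "A", "y": "B"}, {"e0": ("A", "B")})
        assert informativeness_score(ans, kg) == pytest.approx(1.0)

    def test_all_max_degree_is_zero(self):
        kg = tiny_kg([("A", "B"), ("B", "Z"), ("Z", "A")])  # all degree 2
        ans = self.answer_for(kg, {"x": "A", "y": "B"}, {"e0": ("A", "B")})
        assert informativeness_score(ans, kg) == pytest.approx(0.0)

    def test_higher_degree_intermediate_never_scores_higher(self):
        # HUB has degree 4, LEAF has degree 1; same chemical and disease
        kg = tiny_kg(
            [("X", "HUB"), ("HUB", "Y"), ("HUB", "P"), ("HUB", "Q"),
             ("X", "LEAF2"), ("LEAF2", "Y")],
        )
        via_hub = self.answer_for(
            kg, {"c": "X", "g": "HUB", "d": "Y"},
            {"e0": ("X", "HUB"), "e1": ("HUB", "Y")},
        )
        via_leaf = self.answer_for(
            kg, {"c": "X", "g": "LEAF2", "d": "Y"},
            {"e0": ("X", "LEAF2"), "e1": ("LEAF2", "Y")},
        )
        assert informativeness_score(via_hub, kg) <= informativeness_score(via_leaf, kg)

    def test_absent_node_rejected(self, co_fixture):
        kg, _, _ = co_fixture
        ans = AnswerSubgraph(
            node_bindings={"x": C("FIX:GHOST")}, edge_bindings={}
        )
        with pytest.raises(KeyError):
            informativeness_score(ans, kg)


class TestRankAnswers:
    def test_top_answer_is_most_supported_gene(self, co_fixture):
        kg, index, qg = co_fixture
        answers = match_question(kg, qg)
        scored = rank_answers(answers, qg, kg, index)
        assert str(scored[0].answer.node_bindings["gene"]) == "FIX:TNF"
        assert scored[0].supports["e1"].omnicorp_count == 858
        assert scored[0].supports["e0"].omnicorp_count == 44

    def test_scores_within_unit_interval(self, co_fixture):
        kg, index, qg = co_fixture
        scored = rank_answers(match_question(kg, qg), qg, kg, index)
        for s in scored:
            assert 0 < s.confidence < 1
            assert 0 <= s.informativeness <= 1
            assert 0 < s.score <= 1

    def test_identical_evidence_ranks_lexicographically(self):
        kg = tiny_kg(
            [("X", "G1"), ("G1", "Y"), ("X", "G2"), ("G2", "Y")],
            categories={"X": "chemical_substance", "Y": "disease"},
        )
        qg = QuestionGraph(
            qnodes=(
                QNode(qid="chemical", binding=C("FIX:X")),
                QNode(qid="gene", category="gene"),
                QNode(qid="disease", binding=C("FIX:Y")),
            ),
            qedges=(
                QEdge(qeid="e0", source_qid="chemical", target_qid="gene"),
                QEdge(qeid="e1", source_qid="gene", target_qid="disease"),
            ),
        )
        scored = rank_answers(match_question(kg, qg), qg, kg, None)
        genes = [str(s.answer.node_bindings["gene"]) for s in scored]
        assert genes == ["FIX:G1", "FIX:G2"]

    def test_permutation_invariant(self, co_fixture):
        kg, index, qg = co_fixture
        answers = match_question(kg, qg)
        forward = rank_answers(answers, qg, kg, index)
        backward = rank_answers(list(reversed(answers)), qg, kg, index)
        assert [s.answer.sort_key() for s in forward] == [
            s.answer.sort_key() for s in backward
        ]

    def test_more_curated_publications_never_lowers_rank(self, co_fixture):
        kg, index, qg = co_fixture

        def rank_of_bdnf(extra_pubs):
            edges = []
            for e in kg.edges:
                if {e.subject, e.object} == {C("FIX:CO"), C("FIX:BDNF")}:
                    pubs = tuple(f"PMID:x{i}" for i in range(extra_pubs))
                    edges.append(
                        EdgeRecord(
                            subject=e.subject, predicate=e.predicate,
                            object=e.object, primary_source=e.primary_source,
                            curated_publications=pubs,
                        )
                    )
                else:
                    edges.append(e)
            kg2 = KnowledgeGraph(nodes=dict(kg.nodes), edges=edges, ontology=kg.ontology)
            scored = rank_answers(match_question(kg2, qg), qg, kg2, index)
            genes = [str(s.answer.node_bindings["gene"]) for s in scored]
            return genes.index("FIX:BDNF")

        ranks = [rank_of_bdnf(k) for k in (0, 2, 8, 32, 128)]
        assert all(later <= earlier for earlier, later in zip(ranks, ranks[1:]))
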