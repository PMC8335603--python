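import itertools

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kgreason.fixtures import FixtureSpec, make_example_fixture
from kgreason.question_engine import AnswerSubgraph


@pytest.fixture(scope="session")
def co_fixture():
    """Carbon monoxide / multiple sclerosis worked example (seed 1)."""
    return make_example_fixture(FixtureSpec(example_id="carbon_monoxide_ms", seed=1))


@pytest.fixture(scope="session")
def ammonia_fixture():
    return make_example_fixture(FixtureSpec(example_id="ammonia_asthma", seed=1))


@pytest.fixture(scope="session")
def isopropanol_fixture():
    return make_example_fixture(FixtureSpec(example_id="isopropanol_allergy", seed=1))


def brute_force_match(kg, qg):
    """Exhaustive matcher: try every injective assignment of graph nodes
    to question nodes and keep those where every question edge is
    witnessed. Independent of the backtracking implementation."""
    qids = [q.qid for q in qg.qnodes]
    answers = []
    for combo in itertools.permutations(kg.nodes, len(qids)):
        bound = dict(zip(qids, combo))
        ok = True
        for q in qg.qnodes:
            node = kg.nodes[bound[q.qid]]
            if q.binding is not None and q.binding != node.id:
                ok = False
                break
            if q.category is not None and not any(
                kg.ontology.is_subtype(c, q.category) for c in node.categories
            ):
                ok = False
                break
        if not ok:
            continue
        edge_bindings = {}
        for qe in qg.qedges:
            witnesses = tuple(
                sorted(
                    (
                        e
                        for e in kg.edges_between(bound[qe.source_qid], bound[qe.target_qid])
                        if qe.predicate is None or e.predicate == qe.predicate
                    ),
                    key=lambda e: e.key(),
                )
            )
            if not witnesses:
                ok = False
                break
            edge_bindings[qe.qeid] = witnesses
        if ok:
            answers.append(
                AnswerSubgraph(node_bindings=bound, edge_bindings=edge_bindings)
            )
    answers.sort(key=lambda a: a.sort_key())
    return answers


def answers_as_tuples(answers):
    return [tuple(sorted((q, str(c)) for q, c in a.node_bindings.items())) for a in answers]
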