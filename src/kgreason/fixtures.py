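"""Deterministic generators for every input the pipeline consumes.

Three worked-example knowledge graphs encode reported
chemical–gene–disease assertions for carbon monoxide–multiple
sclerosis, ammonia–asthma, and isopropanol–allergic disease: each graph
holds the chemical, the disease, the reported intermediary genes (7, 9
and 3 respectively), one chemical–gene and one gene–disease edge per
gene, and a co-occurrence index carrying the reported abstract counts
on the highlighted edges (e.g. multiple sclerosis–TNF 858, carbon
monoxide–TNF 44, carbon monoxide–multiple sclerosis 25). The direct
chemical–disease link lives only in the co-occurrence index, not as a
graph edge, because it is literature support rather than a curated
assertion. Counts not reported anywhere are filled deterministically
from a seeded range kept strictly below the smallest reported count on
the highlighted answer's edges, so the reported ranking relationships
are preserved by construction; those filler values are artifact
inventions and are marked as such in the fixture metadata.

The module also generates random typed graphs (for matcher oracles),
synthetic abstract corpora, and synthetic survey cohorts with planted
exposure–outcome effects under a logistic outcome model.

All generators are pure functions of their arguments, including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kgreason.assoc_screen import Cohort
from kgreason.kg_store import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    default_ontology,
)
from kgreason.omnicorp_lite import CooccurrenceIndex
from kgreason.question_engine import QEdge, QNode, QuestionGraph

__all__ = [
    "FixtureSpec",
    "EXAMPLE_IDS",
    "make_example_fixture",
    "make_random_kg",
    "make_synthetic_corpus",
    "make_synthetic_cohort",
    "make_survey_cohort",
    "SURVEY_N",
    "SURVEY_CHEMICALS",
    "SURVEY_OUTCOMES",
    "SURVEY_CLASSES",
]


def _fix(local_id: str) -> Curie:
    return Curie(prefix="FIX", local_id=local_id)


@dataclass(frozen=True)
class _Example:
    chemical: tuple[str, str]  # (local id, display name)
    disease: tuple[str, str]
    genes: tuple[str, ...]
    # provenance for specific edges: (endpoint pair) -> sources
    sources: Mapping[tuple[str, str], tuple[str, ...]]
    # curated publications for specific edges
    curated_pubs: Mapping[tuple[str, str], tuple[str, ...]]
    # reported co-occurrence abstract counts, keyed by unordered local-id pair
    stated_counts: Mapping[frozenset, int]
    default_filler_range: tuple[int, int]


_EXAMPLES: dict[str, _Example] = {
    "carbon_monoxide_ms": _Example(
        chemical=("CO", "carbon monoxide"),
        disease=("MS", "multiple sclerosis"),
        genes=("TNF", "BDNF", "IL10", "NGF", "IRF8", "KCNMA1", "CASP8"),
        sources={("CO", "TNF"): ("CTD",), ("TNF", "MS"): ("HETIO", "PHAROS")},
        curated_pubs={},
        stated_counts={
            frozenset({"MS", "TNF"}): 858,
            frozenset({"CO", "TNF"}): 44,
            frozenset({"CO", "MS"}): 25,
        },
        default_filler_range=(5, 40),
    ),
    "ammonia_asthma": _Example(
        chemical=("NH3", "ammonia"),
        disease=("ASTHMA", "asthma"),
        genes=("ADA", "PRKG1", "S100B", "TNF", "MPO", "IL6", "IL1B", "PDE4A", "PARP1"),
        sources={("ADA", "ASTHMA"): ("MONARCH",)},
        curated_pubs={},
        stated_counts={
            frozenset({"NH3", "ASTHMA"}): 93,
            frozenset({"ADA", "ASTHMA"}): 32,
        },
        default_filler_range=(5, 31),
    ),
    "isopropanol_allergy": _Example(
        chemical=("IPA", "isopropanol"),
        disease=("ALLERGY", "allergic disease"),
        genes=("IL6", "TNF", "CSF2"),
        sources={("IPA", "IL6"): ("CTD",), ("IL6", "ALLERGY"): ("PHAROS",)},
        curated_pubs={("IPA", "IL6"): ("PMID:1000001",)},
        stated_counts={
            frozenset({"IPA", "IL6"}): 2,
            frozenset({"IL6", "ALLERGY"}): 79,
        },
        default_filler_range=(1, 1),
    ),
}

EXAMPLE_IDS = tuple(sorted(_EXAMPLES))

_DEFAULT_CHEM_GENE_SOURCE = "CTD"
_DEFAULT_GENE_DISEASE_SOURCE = "PHAROS"
_PREDICATE = "related_to"


@dataclass(frozen=True)
class FixtureSpec:
    """Which worked example to build, under which seed and filler range.

    ``filler_pub_range`` (inclusive) supplies co-occurrence counts for
    edges with no reported value; it must stay strictly below the
    smallest reported count on the highlighted answer's graph edges so
    fillers can never overturn the reported ranking.
    """

    example_id: str
    seed: int = 0
    filler_pub_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.example_id not in _EXAMPLES:
            raise ValueError(
                f"unknown example {self.example_id!r}; valid: {EXAMPLE_IDS}"
            )
        if self.filler_pub_range is not None:
            lo, hi = self.filler_pub_range
            if not (0 <= lo <= hi):
                raise ValueError("filler_pub_range must be a non-negative interval")

    def resolved_filler_range(self) -> tuple[int, int]:
        ex = _EXAMPLES[self.example_id]
        rng = self.filler_pub_range or ex.default_filler_range
        chem, disease = ex.chemical[0], ex.disease[0]
        edge_counts = [
            count
            for pair, count in ex.stated_counts.items()
            if pair != frozenset({chem, disease})  # index-only direct link
        ]
        if edge_counts and rng[1] >= min(edge_counts):
            raise ValueError(
                f"filler range {rng} must stay strictly below the smallest "
                f"reported edge count ({min(edge_counts)})"
            )
        return rng


def make_example_fixture(
    spec: FixtureSpec,
) -> tuple[KnowledgeGraph, CooccurrenceIndex, QuestionGraph]:
    """Build one worked example: graph, co-occurrence index, and question."""
    ex = _EXAMPLES[spec.example_id]
    lo, hi = spec.resolved_filler_range()
    rng = np.random.default_rng(spec.seed)

    chem_id, chem_name = ex.chemical
    dis_id, dis_name = ex.disease
    nodes: dict[Curie, NodeRecord] = {}

    def add_node(local: str, name: str, category: str) -> Curie:
        curie = _fix(local)
        nodes[curie] = NodeRecord(
            id=curie, name=name, categories=frozenset({category})
        )
        return curie

    chem = add_node(chem_id, chem_name, "chemical_substance")
    disease = add_node(dis_id, dis_name, "disease")
    for g in ex.genes:
        add_node(g, g, "gene")

    edges: list[EdgeRecord] = []
    edge_pairs: list[tuple[str, str]] = []
    for g in ex.genes:
        edge_pairs.append((chem_id, g))
        edge_pairs.append((g, dis_id))
    for pair in edge_pairs:
        default_source = (
            _DEFAULT_CHEM_GENE_SOURCE
            if pair[0] == chem_id
            else _DEFAULT_GENE_DISEASE_SOURCE
        )
        for source in ex.sources.get(pair, (default_source,)):
            edges.append(
                EdgeRecord(
                    subject=_fix(pair[0]),
                    predicate=_PREDICATE,
                    object=_fix(pair[1]),
                    primary_source=source,
                    curated_publications=ex.curated_pubs.get(pair, ()),
                )
            )
    kg = KnowledgeGraph(nodes=nodes, edges=edges, ontology=default_ontology())

    index = CooccurrenceIndex()
    # co-occurrence pairs: every graph edge pair plus the direct
    # chemical-disease literature link
    cooc_pairs = sorted(set(edge_pairs)) + [(chem_id, dis_id)]
    for pair in cooc_pairs:
        key = frozenset(pair)
        count = ex.stated_counts.get(key)
        if count is None:
            count = int(rng.integers(lo, hi + 1))
        index.set_pair_count(_fix(pair[0]), _fix(pair[1]), count)

    question = QuestionGraph(
        qnodes=(
            QNode(qid="chemical", binding=chem),
            QNode(qid="gene", category="gene"),
            QNode(qid="disease", binding=disease),
        ),
        qedges=(
            QEdge(qeid="e0", source_qid="chemical", target_qid="gene"),
            QEdge(qeid="e1", source_qid="gene", target_qid="disease"),
        ),
    )
    return kg, index, question


# ---------------------------------------------------------------------------
# Random graphs

_RANDOM_CATEGORIES = ("chemical_substance", "gene", "disease", "phenotypic_feature")
_RANDOM_PREDICATES = ("related_to", "affects", "associated_with")


def make_random_kg(n_nodes: int, n_edges: int, seed: int) -> KnowledgeGraph:
    """Seeded random typed graph over the miniature ontology.

    Edges are sampled without replacement from all (unordered pair,
    predicate) combinations, so parallel edges differ in predicate.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    max_edges = n_nodes * (n_nodes - 1) // 2 * len(_RANDOM_PREDICATES)
    if n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} edges among {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    nodes: dict[Curie, NodeRecord] = {}
    curies = []
    for i in range(n_nodes):
        curie = _fix(f"N{i}")
        cat = _RANDOM_CATEGORIES[int(rng.integers(len(_RANDOM_CATEGORIES)))]
        nodes[curie] = NodeRecord(
            id=curie, name=f"node {i}", categories=frozenset({cat})
        )
        curies.append(curie)
    combos = [
        (i, j, p)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        for p in _RANDOM_PREDICATES
    ]
    chosen = rng.choice(len(combos), size=n_edges, replace=False)
    edges = []
    for k in sorted(int(c) for c in chosen):
        i, j, pred = combos[k]
        edges.append(
            EdgeRecord(
                subject=curies[i],
                predicate=pred,
                object=curies[j],
                primary_source="SYN",
                curated_publications=(),
            )
        )
    return KnowledgeGraph(nodes=nodes, edges=edges, ontology=default_ontology())


# ---------------------------------------------------------------------------
# Synthetic corpora

def make_synthetic_corpus(
    concepts: Sequence[tuple[str, Curie]], n_abstracts: int, seed: int
):
    """Random short abstracts mentioning known concept terms.

    Returns (records, lexicon_entries): each abstract mentions a random
    subset of the given (term, curie) vocabulary amid neutral filler
    words, for exercising annotation and index construction.
    """
    from kgreason.omnicorp_lite import AbstractRecord

    rng = np.random.default_rng(seed)
    filler = ["study", "of", "patients", "with", "observed", "effects", "cells"]
    records = []
    for i in range(n_abstracts):
        k = int(rng.integers(0, len(concepts) + 1))
        picks = rng.choice(len(concepts), size=k, replace=False)
        words = []
        for j in picks:
            words.append(concepts[int(j)][0])
            words.extend(
                rng.choice(filler, size=int(rng.integers(1, 4)), replace=True)
            )
        records.append(
            AbstractRecord(
                pmid=f"PMID:{900000 + i}",
                title=f"synthetic abstract {i}",
                abstract=" ".join(words),
            )
        )
    return records, {term: curie for term, curie in concepts}


# ---------------------------------------------------------------------------
# Synthetic cohorts

# Study conditions the survey generator emulates: 4574 participants,
# 18 workplace chemical classes, 17 immune-mediated conditions.
SURVEY_N = 4574
SURVEY_CHEMICALS = tuple(f"chem_{i:02d}" for i in range(18))
SURVEY_OUTCOMES = tuple(f"imd_{i:02d}" for i in range(17))
SURVEY_CLASSES = {
    f"class_{c}": frozenset(SURVEY_CHEMICALS[3 * c : 3 * c + 3]) for c in range(6)
}


def make_synthetic_cohort(
    n: int,
    exposures: Sequence[str],
    outcomes: Sequence[str],
    planted: Sequence[tuple[str, str, float]] = (),
    exposure_prevalence: float = 0.2,
    outcome_prevalence: float = 0.1,
    missing_rate: float = 0.0,
    seed: int = 0,
    chemical_classes: Mapping[str, frozenset[str]] | None = None,
) -> Cohort:
    """Simulate a survey cohort with optional planted effects.

    Exposures are independent Bernoulli(exposure_prevalence). Each
    outcome follows a logistic model: baseline log-odds give the
    unexposed outcome prevalence, and each planted (exposure, outcome,
    odds_ratio) adds log(odds_ratio) when that exposure is present, so
    the exposed/unexposed odds ratio equals the planted value exactly.
    Missingness is completely at random at ``missing_rate`` per cell.
    """
    if not (0 <= exposure_prevalence <= 1 and 0 < outcome_prevalence < 1):
        raise ValueError("prevalences must be probabilities")
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must lie in [0, 1]")
    for expo, outc, odds_ratio in planted:
        if odds_ratio <= 0:
            raise ValueError("planted odds ratios must be positive")
        if expo not in exposures or outc not in outcomes:
            raise ValueError(f"planted pair ({expo!r}, {outc!r}) not in columns")
    rng = np.random.default_rng(seed)
    expo_mat = (rng.random((n, len(exposures))) < exposure_prevalence).astype(float)
    base_logit = np.log(outcome_prevalence / (1 - outcome_prevalence))
    out_mat = np.empty((n, len(outcomes)))
    expo_idx = {e: i for i, e in enumerate(exposures)}
    planted_by_outcome: dict[str, list[tuple[int, float]]] = {}
    for expo, outc, odds_ratio in planted:
        planted_by_outcome.setdefault(outc, []).append(
            (expo_idx[expo], np.log(odds_ratio))
        )
    for j, outc in enumerate(outcomes):
        logit = np.full(n, base_logit)
        for i_expo, log_or in planted_by_outcome.get(outc, []):
            logit = logit + log_or * expo_mat[:, i_expo]
        prob = 1.0 / (1.0 + np.exp(-logit))
        out_mat[:, j] = (rng.random(n) < prob).astype(float)
    data = np.hstack([expo_mat, out_mat])
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data = np.where(mask, np.nan, data)
    df = pd.DataFrame(
        data,
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id"),
        columns=list(exposures) + list(outcomes),
    )
    return Cohort(
        responses=df,
        exposures=tuple(exposures),
        outcomes=tuple(outcomes),
        chemical_classes=dict(chemical_classes or {}),
    )


def make_survey_cohort(
    seed: int,
    planted: Sequence[tuple[str, str, float]] = (),
    n: int = SURVEY_N,
    missing_rate: float = 0.05,
) -> Cohort:
    """The default survey-scale cohort: 18 chemicals (6 classes of 3),
    17 outcome conditions, 4574 subjects, 5% item missingness."""
    return make_synthetic_cohort(
        n=n,
        exposures=SURVEY_CHEMICALS,
        outcomes=SURVEY_OUTCOMES,
        planted=planted,
        missing_rate=missing_rate,
        seed=seed,
        chemical_classes=SURVEY_CLASSES,
    )
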