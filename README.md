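# kgreason

Desk-scale biomedical knowledge-graph question answering and hypothesis
generation.

Environmental-health studies routinely surface statistical associations —
say, between a self-reported workplace chemical exposure and an
immune-mediated disease — without any mechanistic account of *why* the two
might be linked. `kgreason` closes that loop at desk scale: it screens a
survey cohort for exposure–disease associations, turns each significant hit
into a small template query ("what genes might mediate the association
between chemical X and disease Y?"), matches that query against a typed
knowledge graph of curated biomedical assertions, and ranks the resulting
chemical–gene–disease answer paths by the strength of their literature
support. The target audience is computational biologists and environmental
epidemiologists who want a transparent, fully inspectable version of this
pipeline that runs in seconds on a laptop.

## The model

**Graph and questions.** The knowledge graph is a typed property graph:
nodes are CURIE-identified entities carrying categories from a miniature
upper-level ontology (`named_thing` ⊒ chemical_substance, gene, disease,
phenotypic_feature); edges are provenance-bearing assertions
(subject, predicate, object, primary source, curated publications), with
parallel edges kept when several sources assert the same link. A *question
graph* pins some nodes to CURIEs and constrains others by category; an
*answer* is an injective assignment of graph nodes to question nodes in
which every question edge is witnessed by at least one graph edge
(direction ignored, parallel witnesses pooled into one answer).

**Ranking.** Each question edge of an answer gets support
S = N_curated + ¼·N_cooccur, pooling curated publications with the number
of PubMed abstracts citing both endpoints (from a dictionary-matched
PMID–concept co-occurrence index). Support maps to a conductance via the
saturating weight w = (S+ε)/(S+ε+k), and the answer's confidence is

    confidence = 1 / (1 + R_eff),

where R_eff is the two-terminal effective resistance between the pinned
terminals with each edge's resistance 1/w — series resistances add along a
path, parallel evidence lowers R_eff. An informativeness score
1 − (log d(s) + log d(o)) / (2 log Δ), averaged over edges, penalises
answers routed through high-degree hub nodes, and the final score is the
geometric mean confidence^0.8 · informativeness^0.2.

**Screen.** The upstream association screen cross-tabulates each exposure
(chemical and chemical-class level) against each outcome, tests with
Pearson's chi-square (no continuity correction) or Fisher's exact test when
any expected cell falls below 5, applies one Benjamini–Hochberg FDR
correction across the whole screen, and reports Wald odds ratios
exp(ln(ad/bc) ± 1.96·√(1/a+1/b+1/c+1/d)).

## Worked example

`examples/worked_example_ranking.py` builds the carbon monoxide / multiple
sclerosis example graph (9 nodes, 15 edges, 7 candidate mediating genes)
and ranks the answers:

```
graph: 9 nodes, 15 edges
answers: 7 candidate intermediary genes

#1 score=0.2527 [chemical=FIX:CO, disease=FIX:MS, gene=FIX:TNF]
    resistance=2.9549 confidence=0.2529 informativeness=0.2519
    e0: curated=0 cooccurrence=44 weight=0.5240
    e1: curated=0 cooccurrence=858 weight=0.9555
#2 score=0.2139 [chemical=FIX:CO, disease=FIX:MS, gene=FIX:KCNMA1]
    ...
```

The top-ranked path runs through *TNF*: 44 abstracts co-cite carbon
monoxide with *TNF* (edge e0) and 858 co-cite *TNF* with multiple sclerosis
(edge e1), so its two edges have the highest conductances, the lowest
series resistance (2.95), and the best confidence of the seven candidate
genes; the other genes carry deterministically smaller filler counts and
rank below it. `examples/literature_index.py` shows the co-occurrence
indexing on a three-abstract corpus, and `examples/association_screen.py`
recovers a planted odds-ratio-6 exposure–disease effect from a synthetic
4574-subject survey and emits its follow-up question graph.

The same pipeline is scriptable from the shell:

```sh
kgreason --seed 1 --out out fixtures --example carbon_monoxide_ms
kgreason --out out ask --nodes out/carbon_monoxide_ms.nodes.tsv \
    --edges out/carbon_monoxide_ms.edges.tsv \
    --question out/carbon_monoxide_ms.question.yaml
# out/answers.json now holds the 7 answer subgraphs
```

Subcommands: `fixtures`, `index`, `ask`, `rank`, `screen`, `hypothesize`
(screen → questions → match → rank, end to end), `export-cypher`.

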