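# Methods

## Graph model

The store is a typed property graph. Nodes carry a CURIE (prefix
uppercased on load, local id verbatim, so identifiers join stably across
files), a display name, and a non-empty category set drawn from a
miniature ontology: a forest of category tokens rooted at a universal
`named_thing`, with `is_subtype` defined by the reflexive parent chain.
The shipped ontology has a single level below the root
(chemical_substance, gene, disease, phenotypic_feature); the machinery
supports deeper forests and is property-tested for partial-order
behaviour on them. Edges are stored directed (subject → object) but all
downstream semantics — degree, question matching, resistance — treat
them as undirected, because a chemical–gene–disease answer path is
meaningful regardless of which direction each assertion was curated in.
Parallel edges between the same endpoints are kept distinct so that
"asserted by two sources" remains visible; they are merged only at
scoring time, where their curated publications are unioned.

The Cypher export is deterministic (nodes sorted by CURIE, then edges by
subject/predicate/object) and write-only; the test suite carries its own
minimal round-trip reader to check the export is information-preserving.

## Question matching

Matching is exhaustive backtracking over an injective assignment of
graph nodes to question nodes, expanding the most-constrained question
node (fewest candidates) first and pruning a partial assignment as soon
as a question edge between two bound nodes has no witnessing graph edge.
Injectivity is required because a path answer that binds the same graph
node twice (gene = disease) is meaningless. A pinned CURIE absent from
the graph yields an empty answer set rather than an error: an absent pin
is a legitimate "no answers" outcome for a query written against a
different graph. All parallel witnesses of a question edge are collected
into a single answer's edge bindings — multiple sources strengthen one
answer, they do not multiply it. Output order is lexicographic on the
sorted node bindings, making repeated runs byte-identical. At the
intended scale (tens of nodes, 2–4 question nodes) no indexing is
needed; completeness and soundness are tested against brute-force
enumeration over all injective node tuples.

## Literature co-occurrence

Concept recognition is dictionary-based: text is lowercased and split
into alphanumeric tokens, and a greedy longest-match scan fires the
longest lexicon term starting at each position, consuming its tokens.
Multi-word terms therefore match only on token boundaries ("ada" never
fires inside "adaptation"), and a shorter term nested inside a longer
match is suppressed. Title and abstract are concatenated before
annotation, and at most one link per (PMID, concept) is stored, so a
pair's co-occurrence count is "number of abstracts citing both", not
"number of mentions". This is a deliberately simple stand-in for
ontology-driven named-entity recognition: the downstream contract —
PMID–concept links supporting pairwise counts — is identical, but
abbreviation handling, spelling variants and sense disambiguation are
out of scope, so absolute counts on real text would differ from a
production NER system's.

Fixture builders can also plant a pairwise count directly by minting
synthetic shared PMIDs namespaced by the concept pair; this encodes a
known co-occurrence count without fabricating abstract text.

## Scoring model

Per question edge, support pools the evidence:

    S = w_cur · N_curated + w_omni · N_cooccur,   defaults w_cur = 1, w_omni = 0.25

with N_curated the size of the union of curated publications across
parallel witnesses and N_cooccur the abstract co-occurrence count of the
edge's endpoints. The constraint w_omni ≤ w_cur encodes that a curated
assertion outweighs raw co-occurrence; 0.25 is a design choice (one
curated publication ≈ four co-occurrences), as is the saturating map

    w = (S + ε) / (S + ε + k),   k = 10, ε = 0.01,

which keeps w ∈ (0,1) strictly, so the resistance r = 1/w is finite and
positive even on evidence-free edges, and gives diminishing returns
beyond ~k publications, so one enormous count cannot dominate a whole
multi-edge answer. k = 10 places the half-saturation point at ten
curated publications — a scale at which an assertion is, in practice, no
longer in doubt.

Answer confidence treats each edge's r as an electrical resistance and
computes the two-terminal effective resistance R_eff between the
answer's terminals via the weighted-Laplacian pseudoinverse
(R_eff(s,t) = (e_s−e_t)ᵀL⁺(e_s−e_t)); series edges add, parallel
evidence paths reduce R_eff (Rayleigh monotonicity), and the test suite
checks the Laplacian route against independent series/parallel
closed-form reduction to 1e-9. Terminals are the two pinned question
nodes when exactly two exist; otherwise the mean pairwise effective
resistance over pinned (or, below two pins, all) question-node pairs is
used. Confidence = 1/(1+R_eff) maps (0,∞) monotonically onto (0,1); the
normalisation is a design choice with the convenient fixed point
confidence(R=1) = ½.

Informativeness rewards specific over generic routing: per edge,
1 − (log d(s) + log d(o)) / (2 log Δ) with d the endpoint degree in the
full graph and Δ the graph's maximum degree (clamped to ≥2 so the
denominator is positive), clamped into [0,1] and averaged over the
answer's edges. Degree is used as the graph-intrinsic proxy for
"generic": a hub like *TNF* in a dense immunology graph scores lower
than a rarely-asserted gene. The final score is the weighted geometric
mean confidence^γ · informativeness^(1−γ) with γ = 0.8 —
confidence-dominant, with informativeness as a tiebreaker-strength
modifier; a zero informativeness is floored at ε to keep the score
positive. Ties in score break lexicographically on the sorted bound
CURIEs so rankings are deterministic. Absolute score values are
artifact-defined; only ordering properties (more evidence never ranks
lower, parallel support never hurts) are meaningful, and those are what
the tests pin down.

## Association screen

One 2×2 table per (exposure, outcome) pair, at chemical and
chemical-class level, with pairwise deletion of subjects missing either
variable. A subject is class-exposed if any member chemical is "yes",
class-missing only if no member is "yes" and at least one is missing —
an observed "yes" dominates missingness. Test selection follows
Cochran's rule: Pearson chi-square (no Yates correction) when all
expected cells are ≥ 5 and all margins positive, otherwise Fisher's
exact two-sided test (sum of hypergeometric probabilities ≤ that of the
observed table). One Benjamini–Hochberg family spans the entire screen —
chemical- and class-level tests pooled — and significance is flagged on
the adjusted p at both 0.05 and 0.10. Wald odds-ratio intervals use
z = 1.96 and are reported as undefined (not an error) when any cell is
zero. No covariate adjustment is performed. Degenerate pairs (zero
complete observations) are flagged and excluded from the BH family.

Two cautions surfaced by the test work. First, the uncorrected
chi-square is mildly liberal in small samples: in null screens with
expected case cells around 10, the fraction of whole-screen replicates
with ≥1 FDR-significant hit ran above the nominal 5%; at the survey
scale the screen emulates (n = 4574) it sits at the nominal level. The
null-calibration test therefore runs at that survey scale. Second, the
discrete two-sided Fisher p stays conservative relative to the
chi-square p at moderate p-values regardless of how large the expected
cells are; the two converge under proportional scaling of a fixed
table, which is the property tested.

## Synthetic data

The worked-example fixtures transcribe three reported
chemical–gene–disease answer sets (carbon monoxide–multiple sclerosis
with 7 mediating genes, ammonia–asthma with 9, isopropanol–allergic
disease with 3), their stated provenance (e.g. the multiple
sclerosis–*TNF* link asserted by both HETIO and Pharos, stored as two
parallel edges), and the stated co-occurrence counts (858, 44, 25, 93,
32, 2, 79, plus one curated publication on isopropanol–*IL6*). The
direct chemical–disease link lives only in the co-occurrence index, not
as a graph edge, since it is literature support rather than a curated
assertion. Counts nowhere stated are drawn deterministically from a
seeded per-example filler range kept strictly below the smallest stated
count on that example's highlighted answer edges — [5, 40] for carbon
monoxide, [5, 31] for ammonia, [1, 1] for isopropanol (whose smallest
stated edge count is 2) — so the headline ranking outcome (the
858-abstract *TNF* path on top) holds for every seed, which the tests
exercise. Fixture CURIEs use a local `FIX:` namespace: identifier
authorities are out of scope and the tests need only internal
consistency. One known divergence: with fillers necessarily below 32,
the ammonia example ranks *ADA* first, whereas the reported ranking
placed it last; the source does not state the other eight answers'
counts, so that ordering is not reproducible from the stated numbers and
is not asserted anywhere.

The survey-cohort generator emulates the screen's study conditions: 4574
subjects, 18 chemicals grouped into classes (six classes of three here),
17 outcome conditions, item missingness completely at random at 5%, a
20% exposure prevalence and 10% baseline outcome prevalence. Planted
effects use a logistic outcome model — baseline log-odds give the
unexposed prevalence, each planted pair adds log(OR) when exposed — so
the exposed/unexposed odds ratio equals the planted value exactly, which
is what makes CI-coverage tests well-posed. The generator produces
independent subjects and independent non-planted pairs; real survey data
have correlated exposures, correlated comorbid outcomes, informative
missingness and self-report bias, so passing tests demonstrate the
statistical machinery is correct, not that the screen's operating
characteristics transfer to any particular real cohort.

## Sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen as the package's
own defaults: matcher-oracle equivalence on 100 random graphs of ≤ 20
nodes with 2–4-node questions; resistance-oracle agreement on ≤ 6-node
series-parallel circuits at 1e-9; CI coverage on 200 cohorts of n = 2000
with a planted OR of 2.0; null-screen calibration on 100 replicates at
the emulated survey size. Effective resistance uses a dense
pseudoinverse — answers have a handful of nodes, so numerical rank
issues do not arise. All generators are pure functions of their
arguments including the seed (numpy `default_rng`), and every ranked or
matched output is sorted, so identical configurations give byte-identical
artifacts.

## Limitations

No identifier resolution, no real-source ingestion, no Cypher import, no
query planning for large graphs; dictionary NER only; no covariate
adjustment or survey weighting in the screen; scores are comparable
within one ranking, not across graphs or parameter settings.
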