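"""Build a PMID-concept co-occurrence index from a tiny abstract corpus.

Annotates three abstracts against a term lexicon with greedy
longest-match dictionary recognition, then queries pairwise abstract
co-occurrence counts.
"""

from kgreason.kg_store import Curie
from kgreason.omnicorp_lite import AbstractRecord, Lexicon, build_index

lexicon = Lexicon(
    {
        "carbon monoxide": Curie.parse("FIX:CO"),
        "tnf": Curie.parse("FIX:TNF"),
        "multiple sclerosis": Curie.parse("FIX:MS"),
        "carbon": Curie.parse("FIX:CARBON"),
    }
)
corpus = [
    AbstractRecord("PMID:1", "Carbon monoxide induces TNF release", ""),
    AbstractRecord("PMID:2", "TNF in multiple sclerosis lesions", ""),
    AbstractRecord("PMID:3", "", "Carbon monoxide exposure and multiple sclerosis"),
]
index = build_index(corpus, lexicon)

co, tnf, ms = (Curie.parse(c) for c in ("FIX:CO", "FIX:TNF", "FIX:MS"))
print("links:", sorted((p, str(c)) for p, c in index.links))
print("CO & TNF co-occurrences:", index.cooccurrence_count(co, tnf))
print("TNF & MS co-occurrences:", index.cooccurrence_count(tnf, ms))
print("CO & MS co-occurrences:", index.cooccurrence_count(co, ms))

print(
    "\nEach link is one abstract citing one concept; a pair's count is the\n"
    "number of abstracts citing both. 'carbon monoxide' consumes its two\n"
    "tokens, so the nested term 'carbon' never fires inside it."
)
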