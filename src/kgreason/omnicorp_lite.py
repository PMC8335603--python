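"""Literature co-occurrence index: PMID ↔ concept links from abstracts.

Emulates a literature co-occurrence service — a graph of PubMed
identifiers linked to the concepts mentioned in their titles and
abstracts — at desk scale. Concept recognition is dictionary-based:
a lexicon maps lowercased surface terms to CURIEs, and annotation is
a greedy longest-match scan over case-folded, punctuation-stripped
tokens, so multi-word terms match only on token boundaries ("ada"
never fires inside "adaptation") and a longer match consumes its
tokens, suppressing shorter matches nested inside it.

The index stores at most one link per (PMID, concept); the pairwise
co-occurrence count of two concepts is the number of abstracts citing
both, used downstream as edge evidence.

Formats: corpus as JSON Lines (one object per line with ``pmid``,
``title``, ``abstract``); lexicon as TSV ``term<TAB>curie``; index dump
as sorted TSV ``pmid<TAB>curie``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from kgreason.kg_store import Curie

__all__ = [
    "AbstractRecord",
    "Lexicon",
    "CooccurrenceIndex",
    "annotate_text",
    "build_index",
    "cooccurrence_count",
    "read_corpus",
    "read_lexicon",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not (self.title or self.abstract):
            raise ValueError(f"abstract {self.pmid}: title and abstract both empty")


class Lexicon:
    """Surface term → CURIE dictionary; terms are lowercased on entry."""

    def __init__(self, entries: dict[str, Curie]):
        self._entries: dict[tuple[str, ...], Curie] = {}
        for term, curie in entries.items():
            tokens = tuple(_TOKEN_RE.findall(term.lower()))
            if not tokens:
                raise ValueError(f"lexicon term {term!r} has no tokens")
            if tokens in self._entries:
                raise ValueError(f"duplicate lexicon term {term!r}")
            self._entries[tokens] = curie
        if not self._entries:
            raise ValueError("empty lexicon")
        self.max_len = max(len(t) for t in self._entries)

    def lookup(self, tokens: tuple[str, ...]) -> Curie | None:
        return self._entries.get(tokens)

    def __len__(self) -> int:
        return len(self._entries)


def annotate_text(text: str, lexicon: Lexicon) -> set[Curie]:
    """Concepts whose terms occur in *text* under greedy longest-match.

    The text is lowercased and split into alphanumeric tokens; at each
    position the longest matching lexicon term wins and its tokens are
    consumed, so matches never overlap.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    found: set[Curie] = set()
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        hit_len = 0
        for length in range(min(lexicon.max_len, n - i), 0, -1):
            curie = lexicon.lookup(tuple(tokens[i : i + length]))
            if curie is not None:
                hit, hit_len = curie, length
                break
        if hit is not None:
            found.add(hit)
            i += hit_len
        else:
            i += 1
    return found


@dataclass
class CooccurrenceIndex:
    """Set of (pmid, concept) links with per-concept postings."""

    postings: dict[Curie, set[str]] = field(default_factory=dict)

    @property
    def links(self) -> set[tuple[str, Curie]]:
        return {(pmid, c) for c, pmids in self.postings.items() for pmid in pmids}

    def add_link(self, pmid: str, concept: Curie) -> None:
        self.postings.setdefault(concept, set()).add(pmid)

    def cooccurrence_count(self, a: Curie, b: Curie) -> int:
        """Number of abstracts citing both concepts; symmetric; unknown → 0."""
        pa = self.postings.get(a, set())
        pb = self.postings.get(b, set())
        return len(pa & pb)

    def set_pair_count(self, a: Curie, b: Curie, count: int, tag: str = "SYN") -> None:
        """Plant a pairwise count by minting synthetic shared PMIDs.

        Used by fixture builders to encode a known number of
        co-occurring abstracts without a corpus; the minted PMIDs are
        namespaced by the unordered pair so different pairs never share
        them.
        """
        lo, hi = sorted((str(a), str(b)))
        for i in range(count):
            pmid = f"{tag}:{lo}|{hi}|{i}"
            self.add_link(pmid, a)
            self.add_link(pmid, b)

    def dump_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["pmid", "curie"])
            for pmid, curie in sorted((p, str(c)) for p, c in self.links):
                w.writerow([pmid, curie])


def build_index(corpus: Iterable[AbstractRecord], lexicon: Lexicon) -> CooccurrenceIndex:
    """Annotate every record and collect the PMID–concept links.

    Title and abstract are concatenated before annotation; mentions are
    deduplicated to one link per (pmid, concept). Duplicate PMIDs in the
    corpus are an error. Order-independent: permuting the corpus yields
    the same index.
    """
    index = CooccurrenceIndex()
    seen: set[str] = set()
    for record in corpus:
        if record.pmid in seen:
            raise ValueError(f"duplicate PMID in corpus: {record.pmid}")
        seen.add(record.pmid)
        for concept in annotate_text(record.title + " " + record.abstract, lexicon):
            index.add_link(record.pmid, concept)
    return index


def cooccurrence_count(index: CooccurrenceIndex, a: Curie, b: Curie) -> int:
    """Functional alias for :meth:`CooccurrenceIndex.cooccurrence_count`."""
    return index.cooccurrence_count(a, b)


def read_corpus(path: str | Path) -> list[AbstractRecord]:
    """Read a JSON Lines corpus (fields pmid, title, abstract)."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append(
                AbstractRecord(
                    pmid=str(obj["pmid"]),
                    title=obj.get("title", ""),
                    abstract=obj.get("abstract", ""),
                )
            )
    return records


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a ``term<TAB>curie`` TSV lexicon."""
    entries: dict[str, Curie] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["term", "curie"]:
            raise ValueError(f"{path}: expected header 'term\\tcurie'")
        for row in reader:
            term = row["term"].lower()
            if term in entries:
                raise ValueError(f"{path}: duplicate term {term!r}")
            entries[term] = Curie.parse(row["curie"])
    return Lexicon(entries)
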