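"""Inverted index and TF*IDF ranking over a vocabulary view.

Every atom of every concept is run through the conservative normalization
pipeline and all candidate lemmas of ambiguous tokens are indexed, so a
query can reach a concept through any reading of a form.  Ranking is
coverage-first: a candidate that matches every query lemma always ranks
above one that matches fewer, with the smoothed TF*IDF score breaking
ties and the concept id as the final deterministic tie-break.  No
document-length normalization is applied — concept terms are short and
whole-phrase containment, not verbosity, is what should dominate.

Scores use ``idf(l) = ln((N + 1) / (df(l) + 1)) + 1`` with raw term
frequency, summed with :func:`math.fsum` over lemmas in sorted order so
that independently recomputed scores are bitwise identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import VocabularyView
from .textnorm import (
    EquivalenceTable,
    LemmaBag,
    default_stopwords,
    lemmatize_token,
    normalize_phrase,
    normalize_spelling,
    remove_stopwords,
    strip_paren_tag,
    tokenize,
)

__all__ = [
    "InvertedIndex",
    "RankedCandidate",
    "build_index",
    "phrase_search",
    "single_word_match",
    "batch_search",
]


@dataclass(frozen=True)
class RankedCandidate:
    """One ranked search hit."""

    concept_id: str
    score: float
    coverage: float
    matched_lemmas: FrozenSet[str]


class InvertedIndex:
    """Lemma -> postings index over one vocabulary view.

    Attributes mirror the classic layout: ``postings[lemma][cid]`` is the
    raw term frequency across the concept's atoms, ``n_docs`` the number
    of indexed concepts, ``doc_len[cid]`` the concept's total lemma count.
    Per-atom canonical lemma sets are kept for exact matching, whole-term
    containment tests and the single-word matcher.
    """

    def __init__(
        self,
        equivalences: Optional[EquivalenceTable] = None,
        stoplist: Optional[Iterable[str]] = None,
    ) -> None:
        self.equivalences = equivalences or EquivalenceTable.default()
        self.stoplist = (
            frozenset(stoplist) if stoplist is not None else default_stopwords()
        )
        self.postings: Dict[str, Dict[str, int]] = {}
        self.doc_len: Dict[str, int] = {}
        # per concept: canonical (equivalence-class representative) lemma
        # set of each atom, deduplicated, empty sets dropped
        self._atom_class_sets: Dict[str, Tuple[FrozenSet[str], ...]] = {}
        self._concept_lemmas: Dict[str, FrozenSet[str]] = {}
        self._exact: Dict[FrozenSet[str], str] = {}
        self._one_word: Dict[str, List[str]] = {}
        self._by_class_lemma: Dict[str, Set[str]] = {}

    # -- construction ------------------------------------------------------

    def _index_concept(self, concept) -> None:
        cid = concept.concept_id
        tf: Dict[str, int] = {}
        total = 0
        class_sets: List[FrozenSet[str]] = []
        all_lemmas: Set[str] = set()
        for atom in concept.terms:
            tokens = remove_stopwords(
                tokenize(strip_paren_tag(atom.term)), self.stoplist
            )
            reps: List[str] = []
            for tok in tokens:
                cands = lemmatize_token(normalize_spelling(tok))
                reps.append(min(cands))
                for lemma in sorted(cands):
                    tf[lemma] = tf.get(lemma, 0) + 1
                    total += 1
                all_lemmas |= cands
            if reps:
                class_sets.append(
                    frozenset(self.equivalences.canonical(r) for r in reps)
                )
        self.doc_len[cid] = total
        for lemma, count in tf.items():
            self.postings.setdefault(lemma, {})[cid] = count
        unique_sets = tuple(dict.fromkeys(class_sets))
        self._atom_class_sets[cid] = unique_sets
        self._concept_lemmas[cid] = frozenset(all_lemmas)
        for cset in unique_sets:
            if cset not in self._exact or cid < self._exact[cset]:
                self._exact[cset] = cid
            for lemma in cset:
                self._by_class_lemma.setdefault(lemma, set()).add(cid)
            if len(cset) == 1:
                (lemma,) = cset
                bucket = self._one_word.setdefault(lemma, [])
                if cid not in bucket:
                    bucket.append(cid)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_docs(self) -> int:
        return len(self.doc_len)

    def df(self, lemma: str) -> int:
        return len(self.postings.get(lemma, ()))

    def idf(self, lemma: str) -> float:
        return math.log((self.n_docs + 1) / (self.df(lemma) + 1)) + 1.0

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.doc_len

    def concept_lemmas(self, concept_id: str) -> FrozenSet[str]:
        return self._concept_lemmas[concept_id]

    def atom_class_sets(self, concept_id: str) -> Tuple[FrozenSet[str], ...]:
        return self._atom_class_sets[concept_id]

    def canonicalize(self, lemmas: Iterable[str]) -> FrozenSet[str]:
        """Map lemmas to their equivalence-class representatives."""
        return frozenset(self.equivalences.canonical(l) for l in lemmas)

    def exact_lookup(self, class_set: FrozenSet[str]) -> Optional[str]:
        return self._exact.get(class_set)

    def one_word_concepts(self, class_lemma: str) -> Tuple[str, ...]:
        return tuple(sorted(self._one_word.get(class_lemma, ())))

    def concepts_with_class_lemma(self, class_lemma: str) -> FrozenSet[str]:
        return frozenset(self._by_class_lemma.get(class_lemma, ()))

    # -- scoring -----------------------------------------------------------

    def score(self, query_lemmas: Iterable[str], concept_id: str) -> float:
        """Smoothed TF*IDF score of a concept for a query lemma set.

        The query is expanded through the equivalence table before
        matching; a concept with no matching lemma scores 0.  Unknown
        concept ids raise ``ValueError``.
        """
        if concept_id not in self.doc_len:
            raise ValueError(f"concept {concept_id!r} is not indexed")
        expanded = self.equivalences.expand(set(query_lemmas))
        parts = []
        for lemma in sorted(expanded):
            tf = self.postings.get(lemma, {}).get(concept_id)
            if tf:
                parts.append(tf * self.idf(lemma))
        return math.fsum(parts)

    # -- persistence (optional JSON dump) ----------------------------------

    def dump_json(self, path) -> None:
        payload = {
            "n_docs": self.n_docs,
            "doc_len": self.doc_len,
            "postings": {
                lemma: dict(sorted(post.items()))
                for lemma, post in sorted(self.postings.items())
            },
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)


def build_index(
    view: VocabularyView,
    equivalences: Optional[EquivalenceTable] = None,
    stoplist: Optional[Iterable[str]] = None,
) -> InvertedIndex:
    """Index every atom of every concept in the view; deterministic."""
    index = InvertedIndex(equivalences, stoplist)
    for cid in sorted(view.concept_ids):
        index._index_concept(view[cid])
    return index


def phrase_search(index: InvertedIndex, query: str, k: int = 20) -> List[RankedCandidate]:
    """Rank concepts matching one or more query lemmas.

    Candidates are sorted by (coverage desc, score desc, concept id asc)
    and at most ``k`` are returned.  Coverage counts distinct query lemmas
    (by representative) matched through any candidate reading, including
    equivalence expansion.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    bag = normalize_phrase(query, index.stoplist)
    reps = bag.unique()
    if not reps:
        return []
    matched: Dict[str, Set[str]] = {}
    for rep in reps:
        expanded = index.equivalences.expand(set(bag.alternatives[rep]))
        for lemma in expanded:
            for cid in index.postings.get(lemma, ()):
                matched.setdefault(cid, set()).add(rep)
    all_lemmas = bag.all_lemmas()
    candidates = [
        RankedCandidate(
            concept_id=cid,
            score=index.score(all_lemmas, cid),
            coverage=len(hits) / len(reps),
            matched_lemmas=frozenset(hits),
        )
        for cid, hits in matched.items()
    ]
    candidates.sort(key=lambda c: (-c.coverage, -c.score, c.concept_id))
    return candidates[:k]


def single_word_match(
    index: InvertedIndex, query_lemmas: Iterable[str]
) -> Dict[str, List[str]]:
    """Map each query lemma to concepts having a one-word term for it.

    A concept qualifies for a lemma when it carries an atom whose whole
    lemma set is exactly that lemma's equivalence class representative, so
    "hepatic" finds a concept whose one-word term is "liver".
    """
    out: Dict[str, List[str]] = {}
    for lemma in sorted(set(query_lemmas)):
        canonical = index.equivalences.canonical(lemma)
        out[lemma] = list(index.one_word_concepts(canonical))
    return out


def batch_search(
    index: InvertedIndex,
    queries: Sequence[Tuple[str, str]],
    k: int = 10,
) -> pd.DataFrame:
    """Run :func:`phrase_search` over (code, phrase) pairs.

    Returns a table with columns code, rank, concept_id, score, coverage;
    row blocks follow input order and are identical for identical queries.
    """
    rows = []
    for code, phrase in queries:
        for rank, cand in enumerate(phrase_search(index, phrase, k), start=1):
            rows.append(
                {
                    "code": code,
                    "rank": rank,
                    "concept_id": cand.concept_id,
                    "score": cand.score,
                    "coverage": cand.coverage,
                }
            )
    return pd.DataFrame(rows, columns=["code", "rank", "concept_id", "score", "coverage"])
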