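"""Compositional (post-coordinated) mapping of a source term.

A source term is first checked for an exact/synonym match — a concept
carrying an atom whose whole lemma set equals the term's content lemma
set (after spelling normalization and equivalence expansion).  Failing
that, the term's lemmas are covered by up to three concepts whose terms
are *wholly contained* in the query: restricting the candidate pool to
contained terms is what keeps the subset enumeration tractable where
retrieving every concept sharing a single word would not be.

Full covers are preferred over partial ones, fewer concepts over more,
higher coverage and score over lower, and lexicographic concept ids
settle remaining ties.  Successful covers are classified against a small
grammar of composition patterns (lab test + qualitative result, organism
+ infection, body part + pain, ...) driven by the concepts' semantic
categories and literal trigger words in the source term.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import yaml

from .index import InvertedIndex
from .model import VocabularyView
from .textnorm import normalize_phrase

__all__ = [
    "Cover",
    "MappingResult",
    "PatternRule",
    "OUTCOMES",
    "PATTERN_NAMES",
    "load_pattern_rules",
    "exact_match",
    "candidate_pool",
    "find_covers",
    "classify_pattern",
    "map_term",
]

OUTCOMES = ("EXACT", "COMPOSED_2", "COMPOSED_3", "UNMAPPED")

PATTERN_NAMES = (
    "LAB_QUALIFIER",
    "ORGANISM_INFECTION",
    "MALIGNANCY_STAGE",
    "PHARM_THERAPY",
    "DISEASE_PROPHYLAXIS",
    "BODYPART_PAIN",
    "ORGAN_TOXICITY",
    "NONE",
)

#: Pools larger than this are truncated to the top-scoring concepts before
#: subset enumeration (C(40, 3) subsets is still < 10^4).
MAX_POOL = 40


@dataclass(frozen=True)
class Cover:
    """A candidate decomposition of a query into 1-3 concepts."""

    concept_ids: Tuple[str, ...]
    covered: FrozenSet[str]
    uncovered: FrozenSet[str]
    total_score: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.concept_ids) <= 3:
            raise ValueError("a cover uses between 1 and 3 concepts")
        if self.covered & self.uncovered:
            raise ValueError("covered and uncovered lemma sets overlap")

    @property
    def is_full(self) -> bool:
        return not self.uncovered


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping one source term."""

    source_code: str
    source_term: str
    outcome: str
    targets: Tuple[str, ...]
    pattern: str = "NONE"
    score: float = 0.0
    #: best partial cover, kept for human triage when the term is UNMAPPED
    partial_targets: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = {"EXACT": 1, "COMPOSED_2": 2, "COMPOSED_3": 3, "UNMAPPED": 0}
        if self.outcome not in expected:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if len(self.targets) != expected[self.outcome]:
            raise ValueError(
                f"outcome {self.outcome} requires {expected[self.outcome]} "
                f"targets, got {len(self.targets)}"
            )


@dataclass(frozen=True)
class PatternRule:
    name: str
    category: str
    triggers: Tuple[str, ...]


@lru_cache(maxsize=4)
def _load_rules_cached(path: Optional[str]) -> Tuple[PatternRule, ...]:
    if path is None:
        text = (resources.files("termmap.data") / "pattern_rules.yaml").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, encoding="utf-8") as handle:
            text = handle.read()
    raw = yaml.safe_load(text) or []
    return tuple(
        PatternRule(
            name=str(entry["name"]),
            category=str(entry["category"]),
            triggers=tuple(str(t).lower() for t in entry["triggers"]),
        )
        for entry in raw
    )


def load_pattern_rules(path=None) -> Tuple[PatternRule, ...]:
    """Load composition-pattern rules (packaged grammar by default)."""
    return _load_rules_cached(None if path is None else str(path))


# ---------------------------------------------------------------------------


def _query_class_set(index: InvertedIndex, query_lemmas: Iterable[str]) -> FrozenSet[str]:
    return index.canonicalize(set(query_lemmas))


def exact_match(index: InvertedIndex, term: str) -> Optional[str]:
    """Concept whose some atom's lemma set equals the query's lemma set.

    Comparison happens in equivalence-class space after spelling
    normalization, so "dysphemia" matches a concept carrying "stuttering"
    when the pair is equivalent, and "haematocrit abnormal" matches an
    atom "hematocrit abnormal".  Ties break to the ascending concept id.
    """
    bag = normalize_phrase(term, index.stoplist)
    if not bag:
        return None
    return index.exact_lookup(_query_class_set(index, bag.lemmas))


def candidate_pool(index: InvertedIndex, query_lemmas: Iterable[str]) -> FrozenSet[str]:
    """Concepts with at least one term wholly contained in the query.

    A concept qualifies when some atom's full lemma set (canonicalized
    through the equivalence table) is a non-empty subset of the query's
    lemma set.  This is a superset of the single-word matcher's results.
    """
    qset = _query_class_set(index, query_lemmas)
    if not qset:
        return frozenset()
    narrowed: Set[str] = set()
    for lemma in qset:
        narrowed |= index.concepts_with_class_lemma(lemma)
    pool = {
        cid
        for cid in narrowed
        if any(aset and aset <= qset for aset in index.atom_class_sets(cid))
    }
    return frozenset(pool)


def find_covers(
    index: InvertedIndex,
    pool: Iterable[str],
    query_lemmas: Iterable[str],
    max_size: int = 3,
) -> List[Cover]:
    """Enumerate covers of the query lemmas by <= ``max_size`` concepts.

    If any full cover exists only full covers are returned, otherwise the
    maximal-coverage partial covers.  Sorted by (size asc, coverage desc,
    score desc, ids asc).  Pools above :data:`MAX_POOL` concepts are
    pre-truncated to the top scorers; enumeration is exhaustive below.
    """
    if max_size not in (1, 2, 3):
        raise ValueError("max_size must be 1, 2 or 3")
    query_lemmas = set(query_lemmas)
    qset = _query_class_set(index, query_lemmas)
    contributions: Dict[str, FrozenSet[str]] = {}
    scores: Dict[str, float] = {}
    for cid in pool:
        subsets = [s for s in index.atom_class_sets(cid) if s and s <= qset]
        if not subsets:
            continue
        contributions[cid] = frozenset().union(*subsets)
        scores[cid] = index.score(query_lemmas, cid)
    ranked = sorted(contributions, key=lambda c: (-scores[c], c))[:MAX_POOL]

    covers: List[Cover] = []
    for size in range(1, max_size + 1):
        for combo in combinations(ranked, size):
            ids = tuple(sorted(combo))
            covered = frozenset().union(*(contributions[c] for c in ids))
            covers.append(
                Cover(
                    concept_ids=ids,
                    covered=covered,
                    uncovered=qset - covered,
                    total_score=math.fsum(scores[c] for c in ids),
                )
            )
    if not covers:
        return []
    full = [c for c in covers if c.is_full]
    if full:
        covers = full
    else:
        best = max(len(c.covered) for c in covers)
        covers = [c for c in covers if len(c.covered) == best]
    covers.sort(
        key=lambda c: (
            len(c.concept_ids),
            -len(c.covered),
            -c.total_score,
            c.concept_ids,
        )
    )
    return covers


def classify_pattern(
    cover: Cover,
    view: VocabularyView,
    source_term: str,
    rules: Optional[Sequence[PatternRule]] = None,
) -> str:
    """First composition-pattern rule matching the cover, or NONE.

    A rule fires when the cover holds a concept of the rule's category and
    the source term contains one of the rule's trigger literals (matched
    on word boundaries, case-insensitively).
    """
    rules = load_pattern_rules() if rules is None else rules
    categories = {view[cid].category for cid in cover.concept_ids}
    text = source_term.lower()
    for rule in rules:
        if rule.category not in categories:
            continue
        if any(re.search(rf"\b{re.escape(t)}\b", text) for t in rule.triggers):
            return rule.name
    return "NONE"


def map_term(
    index: InvertedIndex,
    view: VocabularyView,
    code: str,
    term: str,
    max_size: int = 3,
    rules: Optional[Sequence[PatternRule]] = None,
) -> MappingResult:
    """Map one source term to at most ``max_size`` target concepts.

    Exact match first; else the best full cover of two or three concepts;
    else UNMAPPED (the best partial cover, if any, is retained separately
    for triage but never counted as a mapping).
    """
    bag = normalize_phrase(term, index.stoplist)
    if not bag:
        return MappingResult(code, term, "UNMAPPED", ())
    query = set(bag.lemmas)

    cid = exact_match(index, term)
    if cid is not None:
        return MappingResult(
            code, term, "EXACT", (cid,), "NONE", index.score(query, cid)
        )

    pool = candidate_pool(index, query)
    covers = find_covers(index, pool, query, max_size)
    if covers and covers[0].is_full:
        best = covers[0]
        n = len(best.concept_ids)
        outcome = {1: "EXACT", 2: "COMPOSED_2", 3: "COMPOSED_3"}[n]
        pattern = (
            classify_pattern(best, view, term, rules) if n > 1 else "NONE"
        )
        return MappingResult(
            code, term, outcome, best.concept_ids, pattern, best.total_score
        )
    partial = covers[0].concept_ids if covers else ()
    return MappingResult(code, term, "UNMAPPED", (), partial_targets=partial)
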