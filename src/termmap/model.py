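"""Core in-memory containers shared across the package.

A :class:`VocabularyView` is the canonical unit the rest of the package
operates on: a bag of coded concepts from one source vocabulary, each
carrying a preferred term plus any number of synonym/variant atoms.  The
model is deliberately flat — hierarchy is reduced to optional ``parent_ids``
links (one lower-level-term -> preferred-term hop), which is all the audit
scans need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

#: Semantic-category tags used by the compositional pattern grammar.
CATEGORIES = frozenset(
    {
        "LAB_TEST",
        "QUALIFIER",
        "ORGANISM",
        "MALIGNANCY",
        "PHARM_ACTION",
        "DISEASE",
        "BODY_PART",
        "ORGAN_SYSTEM",
        "OTHER",
    }
)

#: Term types understood by the readers.  Anything else is coerced to SY.
TERM_TYPES = ("PT", "LLT", "SY", "FN")


@dataclass(frozen=True)
class SourceAtom:
    """One term string attached to a concept in a source vocabulary."""

    concept_id: str
    term: str
    term_type: str = "SY"
    source: str = ""
    active: bool = True

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError(f"empty term for concept {self.concept_id!r}")


@dataclass
class Concept:
    """A coded unit with exactly one preferred term and N variant atoms."""

    concept_id: str
    preferred_term: str
    terms: List[SourceAtom] = field(default_factory=list)
    source: str = ""
    category: Optional[str] = None
    parent_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.terms:
            self.terms = [
                SourceAtom(self.concept_id, self.preferred_term, "PT", self.source)
            ]

    @property
    def atoms(self) -> Tuple[SourceAtom, ...]:
        return tuple(self.terms)

    def copy(self) -> "Concept":
        return replace(self, terms=list(self.terms))


class VocabularyView:
    """A collection of :class:`Concept` keyed by concept id.

    Lookup by id is total over contained ids (``view[cid]`` raises
    ``KeyError`` otherwise) and iteration order is insertion order, which
    the readers keep equal to file order for determinism.
    """

    def __init__(self, source: str = "", concepts: Iterable[Concept] = ()) -> None:
        self.source = source
        self._concepts: Dict[str, Concept] = {}
        for concept in concepts:
            self.add(concept)

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self._concepts:
            raise ValueError(f"duplicate concept id {concept.concept_id!r}")
        self._concepts[concept.concept_id] = concept

    def get(self, concept_id: str) -> Optional[Concept]:
        return self._concepts.get(concept_id)

    def __getitem__(self, concept_id: str) -> Concept:
        return self._concepts[concept_id]

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[Concept]:
        return iter(self._concepts.values())

    @property
    def concept_ids(self) -> Tuple[str, ...]:
        return tuple(self._concepts)

    @property
    def n_terms(self) -> int:
        return sum(len(c.terms) for c in self._concepts.values())

    def copy(self) -> "VocabularyView":
        return VocabularyView(self.source, (c.copy() for c in self))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"VocabularyView(source={self.source!r}, n={len(self)})"


class FrequencyTable:
    """Per-term record counts, e.g. adverse-event tallies keyed by term code."""

    def __init__(self) -> None:
        self.entries: Dict[str, int] = {}
        self.labels: Dict[str, str] = {}

    def add(self, code: str, count: int, label: str = "") -> None:
        if count < 0:
            raise ValueError(f"negative count for code {code!r}")
        self.entries[code] = self.entries.get(code, 0) + count
        if code not in self.labels:
            self.labels[code] = label

    def total(self) -> int:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def items_by_count(self) -> List[Tuple[str, int]]:
        """Entries sorted by (count desc, code asc) — the selection order."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
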