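"""Thesaurus-integration audit scans.

Three error classes that creep into meta-thesaurus integrations are
detected lexically:

* **missed synonymy** — two concepts whose terms collapse to the same
  aggressive normalization key (spelling variants, derivational variants,
  semantic-tag decorations, word-order differences) are probably one
  concept that was duplicated during integration;
* **qualifier inconsistency** — families of qualitative-result terms
  that mix the high/low axis with the increased/decreased axis without
  carrying both complete pairs (e.g. a "level high" term coexisting with
  "level decreased" but no "level increased") indicate that two distinct
  qualifier axes were treated as interchangeable;
* **lower-level-term generality** — a child term lexically *more
  general* than its parent is probably a plain synonym that should not
  be a separate concept, while a child with extra content words is
  probably a distinct, finer concept.

The scans are deterministic, order-invariant over input concepts, and
purely lexical: semantic synonym pairs are found only when they appear in
the equivalence table, keeping every finding auditable from its evidence
string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .model import VocabularyView
from .textnorm import EquivalenceTable, key_lemma_set, normalization_key, tokenize

__all__ = [
    "AuditFinding",
    "DEFAULT_QUALIFIERS",
    "missed_synonymy_scan",
    "qualifier_consistency_scan",
    "llt_relation_scan",
]

DEFAULT_QUALIFIERS = frozenset(
    {"high", "low", "increased", "decreased", "abnormal", "normal"}
)


@dataclass(frozen=True)
class AuditFinding:
    """One detected anomaly linking one or more concepts."""

    kind: str
    concept_ids: Tuple[str, ...]
    evidence: str
    sources: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        minimum = 2 if self.kind == "MISSED_SYNONYMY" else 1
        if len(set(self.concept_ids)) < minimum:
            raise ValueError(
                f"{self.kind} finding needs >= {minimum} distinct concepts"
            )


def missed_synonymy_scan(
    views: Sequence[VocabularyView],
    stoplist: Optional[Iterable[str]] = None,
    equivalences: Optional[EquivalenceTable] = None,
) -> List[AuditFinding]:
    """Group every atom across the views by normalization key.

    One MISSED_SYNONYMY finding is emitted per key shared by two or more
    distinct concepts; findings are sorted by key.  The evidence string is
    the key itself and regenerates the grouping when fed back through
    :func:`~termmap.textnorm.normalization_key`.
    """
    groups: Dict[str, Set[Tuple[str, str]]] = {}
    for view in views:
        for concept in view:
            for atom in concept.terms:
                key = normalization_key(
                    atom.term, stoplist=stoplist, equivalences=equivalences
                )
                if not key:
                    continue
                groups.setdefault(key, set()).add(
                    (concept.concept_id, concept.source or view.source)
                )
    findings = []
    for key in sorted(groups):
        members = groups[key]
        cids = sorted({cid for cid, _ in members})
        if len(cids) < 2:
            continue
        findings.append(
            AuditFinding(
                kind="MISSED_SYNONYMY",
                concept_ids=tuple(cids),
                evidence=key,
                sources=tuple(sorted({src for _, src in members})),
            )
        )
    return findings


def qualifier_consistency_scan(
    view: VocabularyView,
    qualifiers: FrozenSet[str] = DEFAULT_QUALIFIERS,
) -> List[AuditFinding]:
    """Flag qualifier families mixing the high/low and increased/decreased axes.

    Each preferred term ending in a qualifier word contributes (family
    base, qualifier).  A family is inconsistent when it mixes members of
    {high, low} with members of {increased, decreased} *without* carrying
    both complete pairs — the lexical footprint of treating "high" and
    "increased" as interchangeable synonyms when they are distinct
    (above-range versus risen-from-previous-value).
    """
    families: Dict[str, Set[str]] = {}
    members: Dict[str, Set[str]] = {}
    for concept in view:
        tokens = tokenize(concept.preferred_term)
        if len(tokens) < 2 or tokens[-1] not in qualifiers:
            continue
        base = " ".join(tokens[:-1])
        families.setdefault(base, set()).add(tokens[-1])
        members.setdefault(base, set()).add(concept.concept_id)

    findings = []
    for base in sorted(families):
        quals = families[base]
        has_range = bool(quals & {"high", "low"})
        has_delta = bool(quals & {"increased", "decreased"})
        both_pairs = {"high", "low"} <= quals and {"increased", "decreased"} <= quals
        if has_range and has_delta and not both_pairs:
            findings.append(
                AuditFinding(
                    kind="QUALIFIER_INCONSISTENCY",
                    concept_ids=tuple(sorted(members[base])),
                    evidence=base,
                    sources=(view.source,) if view.source else (),
                )
            )
    return findings


def llt_relation_scan(
    view: VocabularyView,
    stoplist: Optional[Iterable[str]] = None,
    equivalences: Optional[EquivalenceTable] = None,
) -> List[AuditFinding]:
    """Compare each child term's key-lemma set with its parent's.

    A child whose stem set is a strict subset of the parent's is lexically
    *more general* (LLT_GENERALITY: "antimony normal" under "blood
    antimony normal" — probably a synonym, since any-tissue is more
    general than blood).  A child with stems beyond the parent's is
    probably a distinct finer concept (LLT_NARROWER: "diphtheritic
    myocarditis" under "diphtheria").  Equal sets are plain synonyms and
    not flagged; dangling parent links are skipped with a warning.
    """
    findings = []
    for concept in sorted(view, key=lambda c: c.concept_id):
        if not concept.parent_ids:
            continue
        child_set = key_lemma_set(
            concept.preferred_term, stoplist=stoplist, equivalences=equivalences
        )
        for parent_id in concept.parent_ids:
            parent = view.get(parent_id)
            if parent is None:
                warnings.warn(
                    f"concept {concept.concept_id} links to unknown parent "
                    f"{parent_id}; pair skipped",
                    stacklevel=2,
                )
                continue
            parent_set = key_lemma_set(
                parent.preferred_term, stoplist=stoplist, equivalences=equivalences
            )
            extras = child_set - parent_set
            if child_set < parent_set:
                kind = "LLT_GENERALITY"
            elif extras and (child_set & parent_set or child_set > parent_set):
                kind = "LLT_NARROWER"
            else:
                continue
            findings.append(
                AuditFinding(
                    kind=kind,
                    concept_ids=(concept.concept_id, parent_id),
                    evidence="|".join(sorted(child_set)),
                    sources=(view.source,) if view.source else (),
                )
            )
    return findings
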