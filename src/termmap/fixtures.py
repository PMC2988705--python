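"""Seeded synthetic-terminology and frequency-data generator.

Real MedDRA/SNOMED/UMLS content and adverse-event tallies are licensed or
bulky, so every analysis module in this package is exercised against
generated vocabularies with known ground truth instead.  The generator
emulates the features the mapping and audit algorithms key on:

* multi-atom concepts with synonym variants (word-order swaps and
  parenthesized semantic tags);
* planted duplicate concepts produced by transforms the normalizer is
  expected to undo (British respelling, derivational suffixes, tag
  decoration, word order);
* source terms built from one category-typed concept plus a literal
  trigger, following the composition-pattern grammar, including
  three-concept drug-level terms;
* Zipf-like record counts emulating the concentration of real
  adverse-event reporting.

Everything is driven by a single integer seed; identical seeds produce
byte-identical serialized bundles.  A :class:`FixtureManifest` records the
planted ground truth so tests can check recovery instead of plausibility.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .io import write_concept_metadata, write_simple5
from .model import Concept, FrequencyTable, SourceAtom, VocabularyView
from .textnorm import EquivalenceTable, normalization_key

__all__ = [
    "PlantedDuplicate",
    "PlantedComposition",
    "FixtureManifest",
    "DEFAULT_TRANSFORMS",
    "generate_vocabulary",
    "default_category_mix",
    "plant_duplicates",
    "generate_compositional_terms",
    "generate_frequency_data",
    "write_bundle",
]

DEFAULT_TRANSFORMS = ("british_spelling", "derivational", "paren_tag", "word_order")

#: Category population order; OTHER goes last so trigger concepts get the
#: lowest OTHER ids.
_CATEGORY_ORDER = (
    "LAB_TEST",
    "QUALIFIER",
    "ORGANISM",
    "MALIGNANCY",
    "PHARM_ACTION",
    "DISEASE",
    "BODY_PART",
    "ORGAN_SYSTEM",
    "OTHER",
)

# Minimum per-category counts for the default mix: enough one-word concepts
# for every composition pattern plus all twelve trigger concepts.
_BASE_MIN = {
    "LAB_TEST": 2,
    "QUALIFIER": 6,
    "ORGANISM": 1,
    "MALIGNANCY": 1,
    "PHARM_ACTION": 1,
    "DISEASE": 1,
    "BODY_PART": 1,
    "ORGAN_SYSTEM": 1,
    "OTHER": 12,
}

_DRUG_LEVEL_PT = "finding of therapeutic drug level"
_DRUG_LEVEL_SY = "drug level"


@dataclass(frozen=True)
class PlantedDuplicate:
    original_id: str
    duplicate_id: str
    transform: str


@dataclass(frozen=True)
class PlantedComposition:
    source_code: str
    source_term: str
    target_ids: Tuple[str, ...]
    pattern: str


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture bundle."""

    seed: int
    planted_duplicates: List[PlantedDuplicate] = field(default_factory=list)
    planted_compositions: List[PlantedComposition] = field(default_factory=list)
    frequency_spec: Optional[Dict[str, float]] = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted_duplicates": [
                {"original": d.original_id, "duplicate": d.duplicate_id, "transform": d.transform}
                for d in self.planted_duplicates
            ],
            "planted_compositions": [
                {
                    "source_code": c.source_code,
                    "source_term": c.source_term,
                    "target_ids": list(c.target_ids),
                    "pattern": c.pattern,
                }
                for c in self.planted_compositions
            ],
            "frequency_spec": self.frequency_spec,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FixtureManifest":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        return cls(
            seed=raw["seed"],
            planted_duplicates=[
                PlantedDuplicate(d["original"], d["duplicate"], d["transform"])
                for d in raw.get("planted_duplicates", [])
            ],
            planted_compositions=[
                PlantedComposition(
                    c["source_code"],
                    c["source_term"],
                    tuple(c["target_ids"]),
                    c["pattern"],
                )
                for c in raw.get("planted_compositions", [])
            ],
            frequency_spec=raw.get("frequency_spec"),
        )


@lru_cache(maxsize=1)
def _lexicon() -> dict:
    text = (resources.files("termmap.data") / "fixture_lexicon.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def default_category_mix(n_concepts: int) -> Dict[str, int]:
    """Deterministic per-category allocation for ``n_concepts`` total."""
    lex = _lexicon()
    base_total = sum(_BASE_MIN.values())
    if n_concepts < base_total:
        raise ValueError(
            f"default mix needs >= {base_total} concepts; pass category_mix"
        )
    capacity = {
        cat: len(lex["categories"][cat]) for cat in _CATEGORY_ORDER
    }
    capacity["LAB_TEST"] += 1  # the drug-level concept
    capacity["OTHER"] += len(lex["triggers"]) + len(lex["modifiers"]) * len(
        lex["categories"]["OTHER"]
    )
    mix = dict(_BASE_MIN)
    remaining = n_concepts - base_total
    while remaining > 0:
        progressed = False
        for cat in _CATEGORY_ORDER:
            if remaining == 0:
                break
            if mix[cat] < capacity[cat]:
                mix[cat] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            raise ValueError("requested more concepts than the lexicon supports")
    return mix


def _variants(rng: random.Random, term: str) -> List[str]:
    """0-3 synonym variants with the same lemma content as ``term``."""
    out = []
    words = term.split()
    if rng.random() < 0.5:
        tag = rng.choice(("finding", "disorder"))
        out.append(f"{term} ({tag})")
    if len(words) >= 2 and rng.random() < 0.4:
        swapped = " ".join(reversed(words))
        if swapped != term:
            out.append(swapped)
    return out


def generate_vocabulary(
    seed: int,
    n_concepts: int = 80,
    category_mix: Optional[Dict[str, int]] = None,
) -> VocabularyView:
    """Build a deterministic synthetic vocabulary from the packaged lexicon.

    Each concept gets 1-4 atoms (a PT plus tag/word-order variants) and a
    semantic-category tag.  When ``category_mix`` is given it fixes the
    per-category concept counts exactly and ``n_concepts`` is ignored;
    otherwise a default mix covering every composition pattern is used.
    Aggressive normalization keys are kept unique across concepts so that
    the duplicate scan has no accidental collisions.
    """
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    lex = _lexicon()
    rng = random.Random(seed)
    mix = dict(category_mix) if category_mix is not None else default_category_mix(n_concepts)
    equivalences = EquivalenceTable.default()
    view = VocabularyView(source="SNOMEDCT")
    used_keys: set = set()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:06d}"

    def add_concept(term: str, category: str) -> bool:
        key = normalization_key(term, equivalences=equivalences)
        if not key or key in used_keys:
            return False
        used_keys.add(key)
        cid = next_id()
        atoms = [SourceAtom(cid, term, "PT", "SNOMEDCT")]
        atoms += [
            SourceAtom(cid, variant, "SY", "SNOMEDCT")
            for variant in _variants(rng, term)
        ]
        view.add(
            Concept(
                concept_id=cid,
                preferred_term=term,
                terms=atoms,
                source="SNOMEDCT",
                category=category,
            )
        )
        return True

    for category in _CATEGORY_ORDER:
        want = mix.get(category, 0)
        if want <= 0:
            continue
        made = 0
        candidates: List[str] = []
        if category == "LAB_TEST":
            candidates.append(_DRUG_LEVEL_PT)  # handled specially below
        if category == "OTHER":
            candidates.extend(lex["triggers"])
        stems = list(lex["categories"][category])
        if category != "QUALIFIER":  # keep qualifier words in canonical order
            rng.shuffle(stems)
        candidates.extend(stems)
        # two-word spillover for OTHER once single stems run out
        if category == "OTHER":
            modifiers = list(lex["modifiers"])
            for stem in stems:
                for modifier in modifiers:
                    candidates.append(f"{modifier} {stem}")
        for term in candidates:
            if made == want:
                break
            if term == _DRUG_LEVEL_PT:
                cid = next_id()
                view.add(
                    Concept(
                        concept_id=cid,
                        preferred_term=_DRUG_LEVEL_PT,
                        terms=[
                            SourceAtom(cid, _DRUG_LEVEL_PT, "PT", "SNOMEDCT"),
                            SourceAtom(cid, _DRUG_LEVEL_SY, "SY", "SNOMEDCT"),
                        ],
                        source="SNOMEDCT",
                        category="LAB_TEST",
                    )
                )
                used_keys.add(normalization_key(_DRUG_LEVEL_PT, equivalences=equivalences))
                used_keys.add(normalization_key(_DRUG_LEVEL_SY, equivalences=equivalences))
                made += 1
                continue
            if add_concept(term, category):
                made += 1
        if made < want:
            raise ValueError(
                f"lexicon exhausted for category {category}: "
                f"wanted {want}, built {made}"
            )
    return view


# ---------------------------------------------------------------------------
# planted duplicates


def _british_variant(term: str) -> Optional[str]:
    british = _lexicon()["british"]
    words = term.split()
    for i, word in enumerate(words):
        if word in british:
            return " ".join(words[:i] + [british[word]] + words[i + 1 :])
    return None


def _derivational_variant(term: str, reference_key: str) -> Optional[str]:
    words = term.split()
    for i in range(len(words) - 1, -1, -1):
        for suffix in ("y", "ic", "al"):
            candidate_words = list(words)
            candidate_words[i] = words[i] + suffix
            candidate = " ".join(candidate_words)
            if normalization_key(candidate) == reference_key:
                return candidate
    return None


def _transform_term(term: str, transform: str) -> Optional[str]:
    if transform == "british_spelling":
        return _british_variant(term)
    if transform == "derivational":
        return _derivational_variant(term, normalization_key(term))
    if transform == "paren_tag":
        return f"{term} (finding)"
    if transform == "word_order":
        words = term.split()
        if len(words) < 2:
            return None
        reordered = " ".join(reversed(words))
        return reordered if reordered != term else None
    raise ValueError(f"unknown transform {transform!r}")


def plant_duplicates(
    view: VocabularyView,
    seed: int,
    k: int,
    transforms: Sequence[str] = DEFAULT_TRANSFORMS,
) -> Tuple[VocabularyView, List[PlantedDuplicate]]:
    """Clone ``k`` concepts under new ids with key-preserving transforms.

    Each clone's term is a transformed rendition of the original preferred
    term that the aggressive normalizer maps back to the same key, so a
    duplicate scan over the returned view must recover every planted pair.
    Clones carry a distinct source label ("MDR") to emulate a second
    vocabulary feeding the same thesaurus.
    """
    if k < 0 or k > len(view):
        raise ValueError("k must be between 0 and the concept count")
    rng = random.Random(seed)
    new_view = view.copy()
    entries: List[PlantedDuplicate] = []
    used: set = set()
    cids = sorted(view.concept_ids)
    for j in range(k):
        planted = False
        for offset in range(len(transforms)):
            transform = transforms[(j + offset) % len(transforms)]
            eligible = []
            for cid in cids:
                if cid in used:
                    continue
                variant = _transform_term(view[cid].preferred_term, transform)
                if variant is not None:
                    eligible.append((cid, variant))
            if not eligible:
                continue
            cid, variant = eligible[rng.randrange(len(eligible))]
            used.add(cid)
            dup_id = f"D{j + 1:06d}"
            new_view.add(
                Concept(
                    concept_id=dup_id,
                    preferred_term=variant,
                    terms=[SourceAtom(dup_id, variant, "PT", "MDR")],
                    source="MDR",
                    category=view[cid].category,
                )
            )
            entries.append(PlantedDuplicate(cid, dup_id, transform))
            planted = True
            break
        if not planted:
            raise ValueError("no eligible concept left for any transform")
    return new_view, entries


# ---------------------------------------------------------------------------
# planted compositional terms

# (pattern, category, trigger words usable as single-token concepts)
_PATTERN_SPECS = (
    ("LAB_QUALIFIER", "LAB_TEST", ("abnormal", "increased", "decreased", "high", "low", "normal")),
    ("ORGANISM_INFECTION", "ORGANISM", ("infection", "bacteremia", "sepsis")),
    ("MALIGNANCY_STAGE", "MALIGNANCY", ("stage", "recurrent", "metastatic")),
    ("PHARM_THERAPY", "PHARM_ACTION", ("therapy",)),
    ("DISEASE_PROPHYLAXIS", "DISEASE", ("prophylaxis",)),
    ("BODYPART_PAIN", "BODY_PART", ("pain", "inflammation", "injury")),
    ("ORGAN_TOXICITY", "ORGAN_SYSTEM", ("toxicity",)),
)


def _one_word_concepts(view: VocabularyView, category: str) -> List[Tuple[str, str]]:
    out = []
    for concept in view:
        if concept.category != category:
            continue
        words = concept.preferred_term.split()
        if len(words) == 1:
            out.append((concept.concept_id, words[0]))
    return sorted(out)


def _term_lookup(view: VocabularyView) -> Dict[str, str]:
    return {c.preferred_term.lower(): c.concept_id for c in view}


def generate_compositional_terms(
    view: VocabularyView,
    seed: int,
    n_per_pattern: int = 1,
    n_triples: Optional[int] = None,
) -> Tuple[List[Tuple[str, str]], List[PlantedComposition]]:
    """Source terms built from known concept pairs/triples.

    For each of the seven patterns, ``n_per_pattern`` terms concatenate a
    one-word concept of the pattern's category with a trigger word whose
    own concept exists in the view; ``n_triples`` additional drug-level
    terms require three concepts (drug-level finding + drug family +
    qualitative result).  Returns the (code, term) query list plus the
    manifest entries recording intended targets and pattern.  Raises
    ``ValueError`` naming the pattern if a required category or trigger
    concept is missing.
    """
    if n_per_pattern < 0:
        raise ValueError("n_per_pattern must be >= 0")
    n_triples = n_per_pattern if n_triples is None else n_triples
    rng = random.Random(seed)
    lookup = _term_lookup(view)
    queries: List[Tuple[str, str]] = []
    entries: List[PlantedComposition] = []
    counter = 0

    def next_code() -> str:
        nonlocal counter
        counter += 1
        return f"M{counter:05d}"

    if n_per_pattern:
        for pattern, category, trigger_words in _PATTERN_SPECS:
            concepts = _one_word_concepts(view, category)
            if not concepts:
                raise ValueError(f"no one-word {category} concept for pattern {pattern}")
            triggers = [(t, lookup[t]) for t in trigger_words if t in lookup]
            if not triggers:
                raise ValueError(f"no trigger concept available for pattern {pattern}")
            seen = set()
            for i in range(n_per_pattern):
                cid, word = concepts[rng.randrange(len(concepts))]
                trigger, trigger_cid = triggers[rng.randrange(len(triggers))]
                if (cid, trigger) in seen and len(concepts) * len(triggers) > len(seen):
                    # resample once for variety; duplicates are still valid
                    cid, word = concepts[rng.randrange(len(concepts))]
                    trigger, trigger_cid = triggers[rng.randrange(len(triggers))]
                seen.add((cid, trigger))
                queries.append((code := next_code(), f"{word} {trigger}"))
                entries.append(
                    PlantedComposition(
                        source_code=code,
                        source_term=f"{word} {trigger}",
                        target_ids=tuple(sorted((cid, trigger_cid))),
                        pattern=pattern,
                    )
                )

    if n_triples:
        drug_level = next(
            (
                c.concept_id
                for c in view
                if any(a.term.lower() == _DRUG_LEVEL_SY for a in c.terms)
            ),
            None,
        )
        pharm = _one_word_concepts(view, "PHARM_ACTION")
        quals = [
            (cid, word)
            for cid, word in _one_word_concepts(view, "QUALIFIER")
            if word in ("increased", "decreased", "high", "low", "abnormal", "normal")
        ]
        if drug_level is None or not pharm or not quals:
            raise ValueError(
                "drug-level triple terms need the drug-level concept, a "
                "PHARM_ACTION concept and a QUALIFIER concept (pattern LAB_QUALIFIER)"
            )
        for i in range(n_triples):
            pharm_cid, pharm_word = pharm[rng.randrange(len(pharm))]
            qual_cid, qual_word = quals[rng.randrange(len(quals))]
            term = f"{pharm_word} drug level {qual_word}"
            queries.append((code := next_code(), term))
            entries.append(
                PlantedComposition(
                    source_code=code,
                    source_term=term,
                    target_ids=tuple(sorted((drug_level, pharm_cid, qual_cid))),
                    pattern="LAB_QUALIFIER",
                )
            )
    return queries, entries


# ---------------------------------------------------------------------------
# frequency data


def generate_frequency_data(
    seed: int,
    n_codes: int = 1000,
    zipf_s: float = 1.1,
    total_records: int = 100_000,
) -> FrequencyTable:
    """Zipf-like counts: count(rank) ∝ rank^(-s), summing exactly to total.

    Counts are integerized by the largest-remainder method so the table's
    total equals ``total_records`` exactly; ``s = 0`` degenerates to a
    near-uniform distribution (max-min <= 1).  Codes are assigned to ranks
    in seeded shuffled order so input order carries no information.
    """
    if n_codes < 1:
        raise ValueError("n_codes must be >= 1")
    if zipf_s < 0:
        raise ValueError("zipf_s must be >= 0")
    if total_records < 0:
        raise ValueError("total_records must be >= 0")
    rng = random.Random(seed)
    weights = [(rank + 1) ** (-zipf_s) for rank in range(n_codes)]
    total_weight = sum(weights)
    exact = [w / total_weight * total_records for w in weights]
    counts = [int(v) for v in exact]
    remainder = total_records - sum(counts)
    by_fraction = sorted(
        range(n_codes), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in by_fraction[:remainder]:
        counts[i] += 1
    codes = [f"PT{i + 1:05d}" for i in range(n_codes)]
    rng.shuffle(codes)
    table = FrequencyTable()
    for rank, code in enumerate(codes):
        table.add(code, counts[rank], f"synthetic preferred term {code}")
    return table


# ---------------------------------------------------------------------------
# bundle serialization


def write_bundle(
    outdir,
    seed: int,
    n_concepts: int = 80,
    n_duplicates: int = 8,
    n_per_pattern: int = 2,
    n_triples: int = 2,
    n_codes: int = 500,
    zipf_s: float = 1.1,
    total_records: int = 200_000,
) -> FixtureManifest:
    """Generate and serialize a complete fixture bundle.

    Writes ``vocabulary.simple5`` (the mapping target, exercising the
    production reader), ``duplicates.simple5`` (the planted clones as a
    second source vocabulary for the audit scans), ``metadata.csv``
    (categories/parents sidecar), ``frequency.csv``, ``queries.tsv``
    (planted source terms), ``mapped_codes.txt`` (a seeded 60% subset
    emulating already-mapped terms) and ``manifest.yaml``.  Identical
    seeds produce byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    sub = [rng.randrange(2**31) for _ in range(4)]

    base = generate_vocabulary(sub[0], n_concepts)
    combined, duplicates = plant_duplicates(base, sub[1], n_duplicates)
    dup_view = VocabularyView(
        source="MDR",
        concepts=(combined[d.duplicate_id].copy() for d in duplicates),
    )
    queries, compositions = generate_compositional_terms(
        base, sub[2], n_per_pattern, n_triples
    )
    freq = generate_frequency_data(sub[3], n_codes, zipf_s, total_records)

    write_simple5(base, outdir / "vocabulary.simple5")
    write_simple5(dup_view, outdir / "duplicates.simple5")
    write_concept_metadata(base, outdir / "metadata.csv")
    with open(outdir / "frequency.csv", "w", encoding="utf-8") as handle:
        handle.write("code,label,count\n")
        for code in sorted(freq.entries):
            handle.write(f"{code},{freq.labels[code]},{freq.entries[code]}\n")
    with open(outdir / "queries.tsv", "w", encoding="utf-8") as handle:
        handle.write("code\tterm\n")
        for code, term in queries:
            handle.write(f"{code}\t{term}\n")
    mapped_rng = random.Random(seed + 1)
    codes_sorted = sorted(freq.entries)
    mapped = sorted(mapped_rng.sample(codes_sorted, int(0.6 * len(codes_sorted))))
    with open(outdir / "mapped_codes.txt", "w", encoding="utf-8") as handle:
        handle.write("\n".join(mapped) + "\n")

    manifest = FixtureManifest(
        seed=seed,
        planted_duplicates=duplicates,
        planted_compositions=compositions,
        frequency_spec={
            "n_codes": n_codes,
            "zipf_s": zipf_s,
            "total_records": total_records,
        },
    )
    manifest.to_yaml(outdir / "manifest.yaml")
    return manifest
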