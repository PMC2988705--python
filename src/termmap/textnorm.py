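"""Deterministic text pipeline for terminology matching.

The pipeline has two profiles:

* **search-time** (conservative): tokenize, drop stop-words, normalize
  British spellings to American, lemmatize.  Every candidate lemma of an
  ambiguous form participates in matching (union semantics), so "leaves"
  can match either "leaf" or "leave".
* **audit-time** (aggressive): the same steps, plus canonicalization
  through the equivalence table and derivational suffix stripping, folded
  into a sorted, pipe-joined *normalization key*.  Keys are designed so
  that word variants ("feeling guilty" / "feeling guilt (finding)") and
  spelling variants ("serum aluminium level" / "serum aluminum level")
  collide, which is exactly what the duplicate-concept scan wants and
  would be far too loose for relevance ranking.

Lemmatization is an exception-table plus suffix-rule cascade whose
candidates are validated against a packaged lemma lexicon; forms the rules
cannot resolve fall back to a single deterministic detachment, and wholly
unknown forms return themselves.  All functions are pure and idempotent
where documented, so keys can be recomputed from report files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "tokenize",
    "strip_paren_tag",
    "load_stopwords",
    "default_stopwords",
    "remove_stopwords",
    "lemmatize_token",
    "normalize_spelling",
    "EquivalenceTable",
    "expand_equivalences",
    "LemmaBag",
    "normalize_phrase",
    "derivational_stem",
    "normalization_key",
    "key_lemma_set",
]

_WORD_RE = re.compile(r"[a-z0-9]+")
# A single trailing parenthesized word group, e.g. " (disorder)" — the
# SNOMED fully-specified-name convention.
_PAREN_TAG_RE = re.compile(r"\s*\([A-Za-z][A-Za-z ]*\)\s*$")


def tokenize(text: str) -> List[str]:
    """Lowercase and split on whitespace/punctuation; hyphens split too.

    Digits are retained; empty text yields an empty list.
    """
    return _WORD_RE.findall(text.lower())


def strip_paren_tag(term: str) -> str:
    """Remove one trailing parenthesized semantic tag, if present."""
    return _PAREN_TAG_RE.sub("", term, count=1).strip()


# ---------------------------------------------------------------------------
# stop-words


def load_stopwords(path) -> FrozenSet[str]:
    """Read a plain-text stop-word file: one word per line, '#' comments."""
    words = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip().lower()
            if line:
                words.add(line)
    return frozenset(words)


@lru_cache(maxsize=1)
def default_stopwords() -> FrozenSet[str]:
    """The packaged PubMed stop-word set."""
    ref = resources.files("termmap.data") / "pubmed_stopwords.txt"
    with resources.as_file(ref) as path:
        return load_stopwords(path)


def remove_stopwords(
    tokens: Sequence[str], stoplist: Optional[Iterable[str]] = None
) -> List[str]:
    """Order-preserving stop-word filter that never empties a query.

    If every token is a stop-word the original list is returned unchanged,
    so phrases made purely of common words remain searchable.
    """
    stops = default_stopwords() if stoplist is None else set(stoplist)
    kept = [t for t in tokens if t not in stops]
    return kept if kept else list(tokens)


# ---------------------------------------------------------------------------
# lemmatization

_LEMMA_EXCEPTIONS: Dict[str, Tuple[str, ...]] = {
    "leaves": ("leaf", "leave"),
    "feet": ("foot",),
    "teeth": ("tooth",),
    "mice": ("mouse",),
    "men": ("man",),
    "women": ("woman",),
    "children": ("child",),
    "diagnoses": ("diagnosis",),
    "metastases": ("metastasis",),
    "species": ("species",),
    "sera": ("serum",),
    "faeces": ("feces",),
}


@lru_cache(maxsize=1)
def _known_lemmas() -> FrozenSet[str]:
    ref = resources.files("termmap.data") / "lemmas.txt"
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(line)
    for forms in _LEMMA_EXCEPTIONS.values():
        words.update(forms)
    return frozenset(words)


def _rule_candidates(token: str) -> List[str]:
    out: List[str] = []
    n = len(token)
    if token.endswith("ies") and n > 4:
        out.append(token[:-3] + "y")
    if token.endswith("es") and n > 3:
        out.append(token[:-2])
        out.append(token[:-1])
    elif token.endswith("s") and n > 3 and not token.endswith(("ss", "us", "is")):
        out.append(token[:-1])
    if token.endswith("ing") and n > 5:
        stem = token[:-3]
        out.append(stem)
        out.append(stem + "e")
        if len(stem) > 2 and stem[-1] == stem[-2]:
            out.append(stem[:-1])
    if token.endswith("ed") and n > 4:
        stem = token[:-2]
        out.append(stem)
        out.append(token[:-1])  # strip just the 'd' -> restore final 'e'
        if len(stem) > 2 and stem[-1] == stem[-2]:
            out.append(stem[:-1])
    return out


def _fallback(token: str) -> str:
    """Single deterministic detachment for forms the lexicon cannot vet."""
    n = len(token)
    if token.endswith("ies") and n > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "xes", "ches", "shes", "zes", "uses")) and n > 4:
        return token[:-2]
    if token.endswith("es") and n > 3 and not token.endswith("ss"):
        return token[:-1]
    if token.endswith("s") and n > 3 and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    if token.endswith("eed") and n > 4:
        return token[:-1]
    if token.endswith("ing") and n > 5:
        stem = token[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            return stem[:-1]
        return stem
    if token.endswith("ed") and n > 4:
        stem = token[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            return stem[:-1]
        return stem
    return token


def lemmatize_token(token: str) -> Set[str]:
    """Return the candidate lemmas (>= 1) for a lowercase token.

    Ambiguous forms can yield several lemmas ("leaves" -> leaf, leave);
    unknown forms return themselves.  Outputs are fixed points of the
    function, which keeps normalization keys idempotent.
    """
    if token in _LEMMA_EXCEPTIONS:
        return set(_LEMMA_EXCEPTIONS[token])
    known = _known_lemmas()
    if token in known:
        return {token}
    validated = {c for c in _rule_candidates(token) if c in known}
    if validated:
        return validated
    return {_fallback(token)}


# ---------------------------------------------------------------------------
# spelling normalization (British -> American)

_SPELLING_EXCEPTIONS: Dict[str, str] = {
    "aluminium": "aluminum",
    "oedema": "edema",
    "oedematous": "edematous",
    "oesophagus": "esophagus",
    "oesophageal": "esophageal",
    "oestrogen": "estrogen",
    "aetiology": "etiology",
    "anaesthesia": "anesthesia",
}

_AE_OE_RE = re.compile(r"(?<=[a-z])(?:ae|oe)")


def normalize_spelling(token: str) -> str:
    """Rewrite a lowercase token to its American spelling; idempotent.

    The explicit exception map runs first (needed for word-initial "ae"/
    "oe" as in "aluminium", "oedema"); then internal "ae"/"oe" collapse to
    "e" (haematocrit -> hematocrit) and a final "-our" becomes "-or"
    (tumour -> tumor).  Short words like "four" or "hour" are left alone.
    """
    if token in _SPELLING_EXCEPTIONS:
        return _SPELLING_EXCEPTIONS[token]
    t = token
    while True:
        new = _AE_OE_RE.sub("e", t)
        if new == t:
            break
        t = new
    if t.endswith("our") and len(t) >= 6:
        t = t[:-3] + "or"
    return t


# ---------------------------------------------------------------------------
# equivalence expansion


class EquivalenceTable:
    """Sets of mutually substitutable lemmas (hepatic <-> liver, ...).

    The transitive closure of the loaded pairs is taken, so each lemma
    belongs to at most one class.  ``canonical`` maps every member to the
    alphabetically first member of its class, which gives audit keys a
    stable representative.
    """

    def __init__(self, classes: Iterable[Iterable[str]] = ()) -> None:
        merged: List[Set[str]] = []
        for cls in classes:
            cls = {str(l).lower() for l in cls}
            overlapping = [g for g in merged if g & cls]
            for g in overlapping:
                cls |= g
                merged.remove(g)
            merged.append(cls)
        self._classes: Tuple[FrozenSet[str], ...] = tuple(
            sorted((frozenset(c) for c in merged), key=sorted)
        )
        self._index: Dict[str, FrozenSet[str]] = {}
        for cls in self._classes:
            for lemma in cls:
                self._index[lemma] = cls

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "EquivalenceTable":
        return cls([set(p) for p in pairs])

    @classmethod
    def empty(cls) -> "EquivalenceTable":
        return cls(())

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "EquivalenceTable":
        """The packaged equivalence list."""
        ref = resources.files("termmap.data") / "equivalences.tsv"
        pairs = []
        for line in ref.read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise ValueError(f"equivalence line needs two columns: {line!r}")
            pairs.append((cols[0], cols[1]))
        return cls.from_pairs(pairs)

    @classmethod
    def load(cls, path) -> "EquivalenceTable":
        """Read a two-column TSV equivalence file ('#' comments allowed)."""
        pairs = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 2:
                    raise ValueError(f"equivalence line needs two columns: {line!r}")
                pairs.append((cols[0], cols[1]))
        return cls.from_pairs(pairs)

    @property
    def classes(self) -> Tuple[FrozenSet[str], ...]:
        return self._classes

    def class_of(self, lemma: str) -> FrozenSet[str]:
        return self._index.get(lemma, frozenset((lemma,)))

    def canonical(self, lemma: str) -> str:
        return min(self.class_of(lemma))

    def expand(self, lemmas: Iterable[str]) -> Set[str]:
        out: Set[str] = set()
        for lemma in lemmas:
            out |= self.class_of(lemma)
        return out


def expand_equivalences(lemmas: Iterable[str], table: EquivalenceTable) -> Set[str]:
    """Replace each lemma by the union of its equivalence class."""
    return table.expand(lemmas)


# ---------------------------------------------------------------------------
# phrase normalization (search profile)


@dataclass(frozen=True)
class LemmaBag:
    """Normalized content of a phrase.

    ``lemmas`` holds one representative (alphabetically first) lemma per
    content token in phrase order; ``alternatives`` maps each
    representative to the full candidate set of its token, so ambiguous
    forms keep all readings available for matching.
    """

    lemmas: Tuple[str, ...]
    alternatives: Mapping[str, FrozenSet[str]]

    def unique(self) -> FrozenSet[str]:
        return frozenset(self.lemmas)

    def all_lemmas(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for cands in self.alternatives.values():
            out |= cands
        return frozenset(out)

    def __bool__(self) -> bool:
        return bool(self.lemmas)


def normalize_phrase(
    text: str, stoplist: Optional[Iterable[str]] = None
) -> LemmaBag:
    """Run the conservative search-time pipeline over a phrase."""
    tokens = remove_stopwords(tokenize(strip_paren_tag(text)), stoplist)
    reps: List[str] = []
    alternatives: Dict[str, FrozenSet[str]] = {}
    for tok in tokens:
        cands = lemmatize_token(normalize_spelling(tok))
        rep = min(cands)
        reps.append(rep)
        alternatives[rep] = alternatives.get(rep, frozenset()) | frozenset(cands)
    return LemmaBag(tuple(reps), alternatives)


# ---------------------------------------------------------------------------
# audit keys (aggressive profile)

_DERIV_SUFFIXES = ("ish", "ous", "ic", "al", "y")


def derivational_stem(lemma: str) -> str:
    """Strip derivational suffixes (-ish, -ous, -ic, -al, -y) to a stem.

    Stripping repeats until no suffix with a remaining stem of length >= 4
    applies, so the function is idempotent ("radiological" -> "radiolog").
    """
    changed = True
    while changed:
        changed = False
        for suffix in _DERIV_SUFFIXES:
            if lemma.endswith(suffix) and len(lemma) - len(suffix) >= 4:
                lemma = lemma[: -len(suffix)]
                changed = True
                break
    return lemma


def _key_lemmas(
    term: str,
    stoplist: Optional[Iterable[str]],
    equivalences: Optional[EquivalenceTable],
) -> List[str]:
    tokens = tokenize(strip_paren_tag(term))
    if not tokens:
        return []
    lemmas = []
    for tok in remove_stopwords(tokens, stoplist):
        lemma = min(lemmatize_token(normalize_spelling(tok)))
        if equivalences is not None:
            lemma = equivalences.canonical(lemma)
        lemmas.append(derivational_stem(lemma))
    return lemmas


def normalization_key(
    term: str,
    stoplist: Optional[Iterable[str]] = None,
    equivalences: Optional[EquivalenceTable] = None,
) -> str:
    """Aggressive, order-insensitive key for duplicate detection.

    Pipeline: strip one trailing parenthesized tag, tokenize, drop
    stop-words, normalize spelling, lemmatize (alphabetically first lemma
    per token), optionally canonicalize through the equivalence table,
    strip derivational suffixes, then sort unique stems and join with '|'.
    Idempotent: feeding a key back through the function reproduces it.
    """
    return "|".join(sorted(set(_key_lemmas(term, stoplist, equivalences))))


def key_lemma_set(
    term: str,
    stoplist: Optional[Iterable[str]] = None,
    equivalences: Optional[EquivalenceTable] = None,
) -> FrozenSet[str]:
    """The unordered stem set behind :func:`normalization_key`."""
    return frozenset(_key_lemmas(term, stoplist, equivalences))
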