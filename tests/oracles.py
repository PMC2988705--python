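"""Independent brute-force oracles for ranking and cover enumeration.

These recompute scores and covers directly from the raw vocabulary view
(or from atom lemma sets), bypassing the inverted index's bookkeeping, so
they stay independent of the code paths they check.  Floating-point sums
use ``math.fsum`` over sorted lemmas, matching the documented scoring
contract bit for bit.
"""

import math
from itertools import combinations

from termmap.textnorm import (
    lemmatize_token,
    normalize_phrase,
    normalize_spelling,
    remove_stopwords,
    strip_paren_tag,
    tokenize,
)


def concept_term_stats(view):
    """Per-concept lemma frequencies recomputed from raw atom strings."""
    stats = {}
    for concept in view:
        tf = {}
        for atom in concept.terms:
            for tok in remove_stopwords(tokenize(strip_paren_tag(atom.term))):
                for lemma in sorted(lemmatize_token(normalize_spelling(tok))):
                    tf[lemma] = tf.get(lemma, 0) + 1
        stats[concept.concept_id] = tf
    return stats


def brute_force_rank(view, query, equivalences, k):
    """Score and sort every concept: (cid, coverage, score) triples."""
    stats = concept_term_stats(view)
    n_docs = len(stats)
    df = {}
    for tf in stats.values():
        for lemma in tf:
            df[lemma] = df.get(lemma, 0) + 1
    bag = normalize_phrase(query)
    reps = sorted(set(bag.lemmas))
    if not reps:
        return []
    expanded_all = equivalences.expand(set(bag.all_lemmas()))
    out = []
    for cid, tf in stats.items():
        hits = [
            rep
            for rep in reps
            if equivalences.expand(set(bag.alternatives[rep])) & set(tf)
        ]
        if not hits:
            continue
        score = math.fsum(
            tf[lemma] * (math.log((n_docs + 1) / (df[lemma] + 1)) + 1.0)
            for lemma in sorted(expanded_all)
            if lemma in tf
        )
        out.append((cid, len(hits) / len(reps), score))
    out.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return out[:k]


def brute_force_score(view, query_lemmas, concept_id, equivalences):
    """TF*IDF score of one concept recomputed from raw strings."""
    stats = concept_term_stats(view)
    n_docs = len(stats)
    df = {}
    for tf in stats.values():
        for lemma in tf:
            df[lemma] = df.get(lemma, 0) + 1
    tf = stats[concept_id]
    expanded = equivalences.expand(set(query_lemmas))
    return math.fsum(
        tf[lemma] * (math.log((n_docs + 1) / (df[lemma] + 1)) + 1.0)
        for lemma in sorted(expanded)
        if lemma in tf
    )


def brute_force_covers(index, pool, query_lemmas, max_size=3):
    """Exhaustive enumeration over every subset of the pool (no cutoff).

    Returns (ids, covered, uncovered, total_score) tuples in the same
    preference order the implementation promises.
    """
    qset = index.canonicalize(set(query_lemmas))
    contrib = {}
    scores = {}
    for cid in pool:
        subsets = [s for s in index.atom_class_sets(cid) if s and s <= qset]
        if subsets:
            contrib[cid] = frozenset().union(*subsets)
            scores[cid] = index.score(set(query_lemmas), cid)
    covers = []
    for size in range(1, max_size + 1):
        for combo in combinations(sorted(contrib), size):
            covered = frozenset().union(*(contrib[c] for c in combo))
            covers.append(
                (
                    tuple(sorted(combo)),
                    covered,
                    qset - covered,
                    math.fsum(scores[c] for c in sorted(combo)),
                )
            )
    if not covers:
        return []
    full = [c for c in covers if not c[2]]
    if full:
        covers = full
    else:
        best = max(len(c[1]) for c in covers)
        covers = [c for c in covers if len(c[1]) == best]
    covers.sort(key=lambda c: (len(c[0]), -len(c[1]), -c[3], c[0]))
    return covers
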