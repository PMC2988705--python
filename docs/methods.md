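# Methods

## Problem setting

Adverse-event records are coded at the preferred-term (PT) level of a
pre-coordinated vocabulary; the target terminology is compositional, so a
source PT may correspond to one target concept, to a combination of two
or three, or to nothing. The package implements the lexical machinery of
such a mapping effort — candidate retrieval, compositional decomposition,
workload triage — together with audit scans for the integration errors
that accumulate when both vocabularies feed a common meta-thesaurus.
Mapping is directional (pre-coordinated → compositional only); building
well-formed post-coordinated expressions with attribute relationships,
negation, and the reverse mapping direction are out of scope.

## Text normalization

Two profiles share one pipeline (tokenize → stop-word removal → spelling
normalization → lemmatization):

* **Search profile** (conservative). Tokens are lowercased runs of
  `[a-z0-9]`, so hyphens split ("off-label" → off, label). The packaged
  PubMed stop-word list (~130 words) filters tokens, with a guard that
  never empties a query. British spellings rewrite to American via a
  small exception map (needed for word-initial forms such as
  "aluminium"/"oedema"), internal "ae"/"oe" → "e", and final "-our" →
  "-or" on words of ≥6 letters; the function is idempotent. Lemmatization
  is an exception table (irregulars such as leaves → {leaf, leave})
  plus a detachment-rule cascade (-ies/-es/-s, -ing, -ed) whose
  candidates are validated against a packaged lemma lexicon (~200
  entries covering the fixture vocabulary and common clinical words);
  ambiguous forms keep *all* validated lemmas and every candidate is
  indexed and searched (union semantics). Unvalidated forms fall back to
  one deterministic detachment, and wholly unknown forms return
  themselves, so outputs are fixed points.
* **Audit profile** (aggressive). The same steps, then each lemma is
  optionally canonicalized to the alphabetically first member of its
  equivalence class, and derivational suffixes (-ish, -ous, -ic, -al,
  -y) are stripped repeatedly while the remaining stem keeps ≥4
  characters. Sorted unique stems joined with `|` form the
  *normalization key*. Keys are idempotent and word-order-insensitive:
  "feeling guilty" and "feeling guilt (finding)" collide, as do
  "serum aluminium level" / "serum aluminum level". This aggressiveness
  is deliberate for duplicate detection and would be far too loose for
  relevance ranking, which is why the search profile omits it.

The equivalence table ships with the three canonical Greco-Latin pairs
(hepatic/liver, gastric/stomach, neoplasm/tumor) plus a small documented
extension (renal/kidney, cardiac/heart, pulmonary/lung, cerebral/brain,
cutaneous/skin, diphtheria/diphtheritic, dysphemia/stutter); it is a
plain two-column TSV, transitively closed at load, and fully replaceable
by the user. Audit keys consult it so that semantic synonym pairs are
detectable *exactly when they are listed* — the scans make no attempt at
distributional inference, keeping every finding reproducible from its
evidence string.

## Retrieval and ranking

The inverted index stores, per lemma, raw term frequencies across all of
a concept's atoms (synonym terms), with trailing parenthesized semantic
tags stripped before indexing. Ranking uses smoothed TF*IDF,

    idf(l) = ln((N + 1) / (df(l) + 1)) + 1,    score(c) = Σ_l tf(l, c) · idf(l),

summed over equivalence-expanded query lemmas. No document-length
normalization is applied: concept terms are short and near-uniform, and
the quantity that should dominate is *coverage* — the fraction of query
lemmas the concept matches — so candidates sort by (coverage desc, score
desc, concept id asc). Scores are accumulated with `math.fsum` over
lemmas in sorted order, making independently recomputed scores bitwise
identical; the test suite exploits this to require exact rank agreement
with a brute-force scorer. Defaults: top-20 candidates interactively,
top-10 in batch mode.

## Compositional mapping

Retrieving every concept sharing *any* word with the query would flood
the cover search, so the candidate pool is restricted to concepts with
at least one atom *wholly contained* in the query's lemma set (in
equivalence-class space). The single-word matcher is the degenerate
single-lemma case of this rule. Within the pool:

1. **Exact match** — an atom whose whole lemma set equals the query's
   (ties to the lowest concept id) gives outcome EXACT.
2. **Covers** — all subsets of ≤3 pool concepts are enumerated
   (exhaustively for pools ≤40; larger pools are first truncated to the
   top-40 by score, far above anything the fixtures produce). Full
   covers beat partial; preference order is fewer concepts, more
   coverage, higher summed score, lexicographic ids. The size of the
   best full cover fixes the outcome (COMPOSED_2 / COMPOSED_3).
3. **UNMAPPED** otherwise; the best partial cover is retained on the
   result object for human triage but never counted as a mapping.

Covers are classified against an ordered, user-editable YAML grammar of
seven patterns (lab test + qualitative result, organism +
infection/bacteremia/sepsis, malignancy + stage/recurrent/metastatic,
pharmacological action + therapy, disease + prophylaxis, body part +
pain/inflammation/injury, organ system + toxicity). A rule fires when
the cover contains a concept of the rule's semantic category and the raw
source term contains a trigger literal on a word boundary; the first
match wins. Categories come from input metadata (a sidecar CSV for
fixture bundles) — deriving them from a real concept hierarchy is out of
scope. The preference order among competing equal-size full covers is a
package design choice; in the original workflow that adjudication was
human.

## High-frequency subsetting

Codes are ordered by (count desc, code asc); the shortest prefix whose
cumulative count reaches the target share (default 0.95, the threshold
used by vocabulary CORE-subset efforts) is extended with all codes tied
at the final count, so the selection is expressible as "every code with
≥ T records". Workload summaries report unique/mapped/high-frequency
counts with percentages rounded half-up to one decimal, matching the
printed precision of published workload tables.

## Audit scans

* **Missed synonymy**: atoms across any number of vocabulary views are
  grouped by normalization key; every key shared by ≥2 concepts yields a
  finding whose evidence *is* the key (feeding it back through the
  normalizer regenerates the group).
* **Qualifier consistency**: preferred terms ending in a qualifier word
  ({high, low, increased, decreased, abnormal, normal}, configurable)
  are grouped by their base; a family mixing the high/low (above/below
  range) axis with the increased/decreased (changed-from-previous) axis
  without carrying both complete pairs is flagged. This operationalizes
  a distinction that compositional terminologies maintain in separate
  sub-hierarchies but loosely-curated sources blur; the rule is a
  lexical surrogate for what is ultimately a curation judgment.
* **LLT relations**: for each child→parent link, audit-key stem sets are
  compared. Child ⊂ parent means the child is lexically more general —
  with a one-level hierarchy that is evidence of plain synonymy
  ("antimony normal" under "blood antimony normal"). Child stems beyond
  the parent's (with overlap) mark a probable distinct finer concept
  ("diphtheritic myocarditis" under "diphtheria", which needs the
  diphtheria/diphtheritic equivalence to register the overlap).

## Synthetic fixtures

The generator emulates exactly the features the algorithms key on, with
a ~200-stem medical lexicon packaged in-repo so outputs stay readable:

* **Vocabularies**: concepts per semantic category (lab analytes,
  qualifiers, organisms, malignancies, drug classes, diseases, body
  parts, organ systems, miscellaneous findings), 1–4 atoms each
  (semantic-tag and word-order variants), one stem per concept and a
  global uniqueness check on audit keys so the duplicate scan has a
  clean baseline. Twelve trigger-word concepts (infection, sepsis,
  pain, toxicity, …) and a multi-atom "finding of therapeutic drug
  level" concept are always generated first so every pattern is
  instantiable. The default mix for n=80 covers all categories.
* **Planted duplicates**: clones under fresh ids whose terms are
  transformed by British respelling (inverse of the spelling rules),
  mechanical derivational suffixation (word + -y/-ic/-al, checked to
  round-trip through the normalizer — this produces unnatural but
  faithfully recoverable forms), tag decoration, or word-order
  reversal. Recovery is recall/precision 1.0 *by construction on these
  transform classes*; real missed synonymy also includes abbreviation
  and free paraphrase, which no lexical normalizer recovers, so passing
  fixtures bound what the scan can do on real data rather than promise
  it.
* **Compositional terms**: one-word category concepts concatenated with
  trigger words (2-concept targets) and drug-family + "drug level" +
  qualifier terms (3-concept targets), with the intended target ids and
  pattern recorded in a YAML manifest.
* **Frequencies**: counts ∝ rank^(−s) integerized by largest remainder
  to sum exactly to the requested total, with seeded code-label
  shuffling. Default s = 1.1; note that reaching a 95% share at s = 1.1
  over 1000 codes takes ~58% of the codes (closed-form property of the
  Zipf tail) — the concentration seen in real adverse-event data
  (15–28% of unique terms) corresponds to s ≈ 1.5, which is what the
  concentration sanity test uses.

Bundles are byte-identical for identical seeds. The fixture realism
boundary: no reporting biases, no hierarchy deeper than one LLT→PT
level, no homonymy, and synthetic frequency counts are independent of
term content.

## Numerical and determinism choices

All randomness flows from explicit integer seeds through
`random.Random`; no global state. Every sort has a total deterministic
key ending in concept id or code. Percentages round half-up via
`decimal`; scores use `math.fsum` over sorted lemmas. Degenerate inputs
are defined rather than rejected where sensible: empty concept files
give empty views, empty queries map to UNMAPPED, an all-stop-word query
is searched unfiltered; empty frequency tables are an error for subset
selection.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: vocabularies of 5–80 concepts, 200 random ranking cases and
100 random cover cases against brute-force oracles, 10 planted
duplicates and 16–24 planted compositions per run, and frequency tables
of 200–1000 codes. These sizes make every enumeration exhaustive (the
oracle regime) while keeping a full run around a second; the algorithms
themselves have no fixture-size assumptions beyond the documented
top-40 pool truncation.
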