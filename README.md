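# termmap

A terminology cross-mapping workbench for pharmacovigilance informatics.

Adverse-event reports are coded with MedDRA preferred terms (PTs) — a
pre-coordinated, five-level vocabulary — while clinical documentation is
moving toward SNOMED CT, a large compositional terminology. The UMLS
meta-thesaurus records only partial, strictly one-to-one correspondences
between the two, even though many MedDRA terms (e.g. "HAEMATOCRIT
ABNORMAL") only exist in SNOMED CT as a *combination* of concepts.
`termmap` implements the software side of a mapping effort between such
vocabularies:

* **Lexical concept search** — an inverted index over lemmatized concept
  terms with PubMed stop-word removal, British→American spelling
  normalization, Greco-Latin equivalence expansion (hepatic/liver,
  gastric/stomach, neoplasm/tumor, …) and TF*IDF ranking,
  `score(c) = Σ_l tf(l, c) · (ln((N+1)/(df(l)+1)) + 1)`,
  sorted coverage-first so whole-phrase matches dominate. A parallel
  single-word matcher finds concepts for the individual words of a phrase.
* **Compositional mapping** — each source term is resolved to an exact
  synonym match, or to a cover of its content lemmas by at most **three**
  target concepts, classified against a grammar of composition patterns
  (⟨lab test⟩ ⟨qualitative result⟩; ⟨organism⟩ "infection"/"sepsis";
  ⟨body part⟩ "pain"; ⟨disease⟩ "prophylaxis"; …) and binned into
  EXACT / COMPOSED_2 / COMPOSED_3 / UNMAPPED.
* **High-frequency subsetting** — selection of the minimal set of term
  codes that accounts for ≥95% of records in an adverse-event frequency
  table (ties at the cut-off count included), plus workload summaries.
* **Thesaurus-integration audits** — detection of duplicated concepts via
  aggressive normalization keys (missed synonymy), qualifier families that
  confuse the high/low axis with increased/decreased, and lower-level
  terms that are lexically more general (probable synonyms) or more
  specific (probable distinct concepts) than their parents.

Licensed vocabularies are **not** required: a seeded fixture generator
produces synthetic vocabularies, planted duplicates, pattern-constructed
source terms and Zipf-distributed frequency tables with a ground-truth
manifest, and everything is validated by planted-truth recovery and
brute-force oracle equivalence.

## Worked example

```sh
termmap simulate --seed 7 -o fx           # synthetic bundle + manifest
termmap batch-map --vocab fx/vocabulary.simple5 --metadata fx/metadata.csv \
    --queries fx/queries.tsv -o fx/report.tsv
head -4 fx/report.tsv
```

```
source_code	source_term	outcome	target_ids	pattern	score
M00001	albumin decreased	COMPOSED_2	S000005;S000013	LAB_QUALIFIER	14.103906
M00002	hematocrit decreased	COMPOSED_2	S000008;S000013	LAB_QUALIFIER	9.402604
M00003	proteus infection	COMPOSED_2	S000022;S000063	ORGANISM_INFECTION	14.103906
```

Each row maps one synthetic source term: "albumin decreased" has no
single target concept, but is fully covered by the lab-test concept
`S000005` ("albumin") plus the qualifier concept `S000013` ("decreased")
— a two-concept composition matching the ⟨lab test⟩ ⟨qualitative result⟩
pattern; the score is the summed TF*IDF relevance of the cover. The
bundle's `manifest.yaml` records the intended targets, and every planted
term maps back to exactly those.

```sh
termmap audit --vocab fx/vocabulary.simple5 --vocab fx/duplicates.simple5 \
    -o fx/audit.tsv
termmap summary --freq fx/frequency.csv --mapped fx/mapped_codes.txt
```

The audit report lists one `MISSED_SYNONYMY` row per planted duplicate
pair, naming the normalization key the terms collide on:

```
kind	evidence	concept_ids	sources
MISSED_SYNONYMY	acinetobacter	D000008;S000021	MDR;SNOMEDCT
MISSED_SYNONYMY	antibiot	D000006;S000037	MDR;SNOMEDCT
MISSED_SYNONYMY	drug|finding|level|therapeut	D000004;S000001	MDR;SNOMEDCT
```

and the summary prints the record/term/mapped/high-frequency workload
table with percentages (here on the bundle's synthetic Zipf counts):

```
A. Number of records in data set	200000
B. Unique preferred terms in data set	500
C. Unique terms already mapped to target terminology	300 (60.0%)
D. High-frequency terms (collectively >= share of records)	315 (63.0%)
E. High-frequency terms already mapped	190 (60.3%)
F. Number needing manual mapping (D-E)	125
```

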