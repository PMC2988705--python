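"""Compositional mapping: exact matches, covers, patterns, outcomes."""

import random

import pytest

from conftest import make_concept, make_view
from oracles import brute_force_covers
from termmap.compose import (
    MappingResult,
    candidate_pool,
    classify_pattern,
    exact_match,
    find_covers,
    load_pattern_rules,
    map_term,
)
from termmap.fixtures import (
    generate_compositional_terms,
    generate_vocabulary,
    plant_duplicates,
)
from termmap.index import build_index
from termmap.textnorm import lemmatize_token, normalize_spelling


def _lemmas(*words):
    return {min(lemmatize_token(normalize_spelling(w))) for w in words}


class TestExactMatch:
    def test_synonym_atom_matches(self):
        view = make_view(make_concept("C0038506", "stuttering", "dysphemia"))
        index = build_index(view)
        assert exact_match(index, "dysphemia") == "C0038506"

    def test_equivalence_class_matches_without_atom(self):
        # "dysphemia" and "stutter" share an equivalence class
        view = make_view(make_concept("C0038506", "stuttering"))
        index = build_index(view)
        assert exact_match(index, "dysphemia") == "C0038506"

    def test_no_match_returns_none(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        assert exact_match(index, "zebra crossing") is None

    def test_spelling_variant_matches(self):
        view = make_view(make_concept("C1", "hematocrit abnormal"))
        index = build_index(view)
        assert exact_match(index, "HAEMATOCRIT ABNORMAL") == "C1"

    def test_tie_breaks_to_lowest_id(self):
        view = make_view(
            make_concept("C2", "sepsis"), make_concept("C1", "sepsis (disorder)")
        )
        index = build_index(view)
        assert exact_match(index, "sepsis") == "C1"


class TestCandidatePool:
    def test_contained_terms_included(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        pool = candidate_pool(index, _lemmas("hematocrit", "abnormal"))
        assert {"S001", "S002"} <= pool

    def test_term_with_extra_lemma_excluded(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        pool = candidate_pool(index, _lemmas("hematocrit", "abnormal"))
        assert "S003" not in pool  # "hematocrit low" brings a lemma outside the query

    def test_empty_query_empty_pool(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        assert candidate_pool(index, set()) == frozenset()

    def test_superset_of_single_word_matches(self):
        from termmap.index import single_word_match

        view = generate_vocabulary(21, 40)
        index = build_index(view)
        query = _lemmas("sepsis", "pain", "hematocrit")
        pool = candidate_pool(index, query)
        for cids in single_word_match(index, query).values():
            assert set(cids) <= pool


class TestFindCovers:
    def test_two_concept_full_cover(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        query = _lemmas("hematocrit", "abnormal")
        covers = find_covers(index, candidate_pool(index, query), query)
        assert covers[0].concept_ids == ("S001", "S002")
        assert covers[0].is_full

    def test_three_concept_drug_level_cover(self):
        view = make_view(
            make_concept(
                "S100", "finding of therapeutic drug level", "drug level",
                category="LAB_TEST",
            ),
            make_concept("S101", "anticonvulsant", category="PHARM_ACTION"),
            make_concept("S102", "decreased", category="QUALIFIER"),
        )
        index = build_index(view)
        query = _lemmas("anticonvulsant", "drug", "level", "decreased")
        covers = find_covers(index, candidate_pool(index, query), query)
        assert covers[0].concept_ids == ("S100", "S101", "S102")
        assert covers[0].is_full

    def test_empty_pool_empty_list(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        assert find_covers(index, frozenset(), {"zebra"}) == []

    def test_matches_exhaustive_enumeration_on_random_pools(self):
        """Cover search equals brute-force subset enumeration (pools <= 12)."""
        rng = random.Random(77)
        for _ in range(60):
            view = generate_vocabulary(rng.randrange(2**31), category_mix={"OTHER": 12})
            index = build_index(view)
            words = [
                c.preferred_term.split()[0]
                for c in rng.sample(list(view), k=rng.randint(2, 5))
            ]
            query = _lemmas(*words)
            pool = candidate_pool(index, query)
            assert len(pool) <= 12
            mine = [
                (c.concept_ids, c.covered, c.uncovered, c.total_score)
                for c in find_covers(index, pool, query)
            ]
            assert mine == brute_force_covers(index, pool, query)


class TestClassifyPattern:
    def _cover(self, *ids):
        from termmap.compose import Cover

        return Cover(tuple(ids), frozenset({"x"}), frozenset(), 1.0)

    def test_organism_plus_sepsis(self, lab_qualifier_view):
        cover = self._cover("S004", "S005")
        assert (
            classify_pattern(cover, lab_qualifier_view, "escherichia sepsis")
            == "ORGANISM_INFECTION"
        )

    def test_bodypart_plus_pain(self):
        view = make_view(
            make_concept("B1", "knee", category="BODY_PART"),
            make_concept("B2", "pain", category="OTHER"),
        )
        cover = self._cover("B1", "B2")
        assert classify_pattern(cover, view, "knee pain") == "BODYPART_PAIN"

    def test_other_concepts_no_pattern(self):
        view = make_view(
            make_concept("O1", "nausea", category="OTHER"),
            make_concept("O2", "fatigue", category="OTHER"),
        )
        cover = self._cover("O1", "O2")
        assert classify_pattern(cover, view, "nausea fatigue") == "NONE"

    def test_rule_order_lab_first(self, lab_qualifier_view):
        # LAB_TEST + qualifier trigger fires the first rule in the grammar
        cover = self._cover("S001", "S002")
        assert (
            classify_pattern(cover, lab_qualifier_view, "hematocrit abnormal")
            == "LAB_QUALIFIER"
        )

    def test_rules_loadable_from_packaged_yaml(self):
        rules = load_pattern_rules()
        assert [r.name for r in rules] == [
            "LAB_QUALIFIER",
            "ORGANISM_INFECTION",
            "MALIGNANCY_STAGE",
            "PHARM_THERAPY",
            "DISEASE_PROPHYLAXIS",
            "BODYPART_PAIN",
            "ORGAN_TOXICITY",
        ]


class TestMapTerm:
    def test_planted_synonym_is_exact(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        result = map_term(index, lab_qualifier_view, "P1", "haematocrit")
        assert result.outcome == "EXACT"
        assert result.targets == ("S001",)

    def test_organism_sepsis_composed_two(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        result = map_term(index, lab_qualifier_view, "P1", "escherichia sepsis")
        assert result.outcome == "COMPOSED_2"
        assert set(result.targets) == {"S004", "S005"}
        assert result.pattern == "ORGANISM_INFECTION"

    def test_novel_lemmas_unmapped(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        result = map_term(index, lab_qualifier_view, "P1", "quetzal plumage syndrome")
        assert result.outcome == "UNMAPPED"
        assert result.targets == ()

    def test_partial_cover_reported_but_unmapped(self, lab_qualifier_view):
        index = build_index(lab_qualifier_view)
        result = map_term(index, lab_qualifier_view, "P1", "hematocrit zebra")
        assert result.outcome == "UNMAPPED"
        assert result.targets == ()
        assert result.partial_targets == ("S001",)

    def test_outcome_targets_invariant_enforced(self):
        with pytest.raises(ValueError):
            MappingResult("P", "t", "EXACT", ())
        with pytest.raises(ValueError):
            MappingResult("P", "t", "COMPOSED_2", ("a", "b", "c"))


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [1, 17, 4242])
    def test_all_planted_compositions_recovered(self, seed):
        """Terms built from known pairs/triples map back to their targets."""
        view = generate_vocabulary(seed, 80)
        index = build_index(view)
        queries, planted = generate_compositional_terms(view, seed + 1, 2, 2)
        assert len(queries) == 7 * 2 + 2
        for (code, term), truth in zip(queries, planted):
            result = map_term(index, view, code, term)
            assert tuple(sorted(result.targets)) == truth.target_ids, term
            assert result.pattern == truth.pattern, term
            expected = {2: "COMPOSED_2", 3: "COMPOSED_3"}[len(truth.target_ids)]
            assert result.outcome == expected

    def test_never_more_than_three_targets(self):
        view = generate_vocabulary(33, 80)
        combined, _ = plant_duplicates(view, 34, 6)
        index = build_index(combined)
        queries, _ = generate_compositional_terms(view, 35, 2, 2)
        probes = [t for _, t in queries]
        probes += [c.preferred_term for c in combined]
        probes += ["hematocrit sepsis pain unknownword", "", "the of"]
        for term in probes:
            result = map_term(index, combined, "P", term)
            assert len(result.targets) <= 3

    def test_outcome_partition_sums_to_batch_size(self):
        from termmap.subset import outcome_tally

        view = generate_vocabulary(55, 80)
        index = build_index(view)
        queries, _ = generate_compositional_terms(view, 56, 1, 1)
        terms = [t for _, t in queries] + ["stuttering", "zebra", "hematocrit"]
        results = [map_term(index, view, f"P{i}", t) for i, t in enumerate(terms)]
        tally = outcome_tally(results)
        assert sum(tally.values()) == len(results)
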