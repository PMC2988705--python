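"""Inverted index construction, scoring and ranking."""

import math
import random

import pytest

from conftest import make_concept, make_view
from oracles import brute_force_rank, brute_force_score
from termmap.fixtures import generate_vocabulary
from termmap.index import batch_search, build_index, phrase_search, single_word_match


class TestBuildIndex:
    def test_single_concept_postings(self):
        index = build_index(make_view(make_concept("C1", "stuttering")))
        assert index.n_docs == 1
        assert index.postings["stutter"] == {"C1": 1}

    def test_term_frequency_across_atoms(self):
        view = make_view(
            make_concept("C1328407", "hip dysplasia", "congenital acetabular dysplasia")
        )
        index = build_index(view)
        assert index.df("dysplasia") == 1
        assert index.postings["dysplasia"]["C1328407"] == 2

    def test_empty_view(self):
        index = build_index(make_view())
        assert index.n_docs == 0
        assert index.postings == {}

    def test_ambiguous_token_indexes_all_lemmas(self):
        index = build_index(make_view(make_concept("C1", "leaves")))
        assert "leaf" in index.postings and "leave" in index.postings

    def test_deterministic_for_fixed_input(self):
        view = generate_vocabulary(3, 40)
        a, b = build_index(view), build_index(view)
        assert a.postings == b.postings
        assert a.doc_len == b.doc_len


class TestScore:
    def test_closed_form_single_concept(self):
        index = build_index(make_view(make_concept("C1", "stuttering")))
        assert index.score({"stutter"}, "C1") == pytest.approx(
            1.0 * (math.log(2 / 2) + 1)
        )

    def test_absent_lemma_scores_zero(self):
        index = build_index(make_view(make_concept("C1", "stuttering")))
        assert index.score({"zebra"}, "C1") == 0.0

    def test_unknown_concept_raises(self):
        index = build_index(make_view(make_concept("C1", "stuttering")))
        with pytest.raises(ValueError):
            index.score({"stutter"}, "C999")

    def test_matches_brute_force_on_three_concept_fixture(self, equivalences):
        view = make_view(
            make_concept("C1", "hematocrit abnormal"),
            make_concept("C2", "hematocrit low", "hematocrit decreased"),
            make_concept("C3", "abnormal"),
        )
        index = build_index(view)
        for cid in view.concept_ids:
            expected = brute_force_score(
                view, {"hematocrit", "abnormal"}, cid, equivalences
            )
            assert index.score({"hematocrit", "abnormal"}, cid) == expected


class TestPhraseSearch:
    def test_self_retrieval_ranks_first(self):
        view = generate_vocabulary(5, 50)
        index = build_index(view)
        for concept in view:
            hits = phrase_search(index, concept.preferred_term, 5)
            assert hits and hits[0].concept_id == concept.concept_id
            assert hits[0].coverage == 1.0

    def test_coverage_dominates_score(self):
        view = make_view(
            make_concept("A1", "hematocrit abnormal"),
            # mentions "hematocrit" many times -> higher tf, lower coverage
            make_concept(
                "B1", "hematocrit", "hematocrit measurement", "hematocrit test"
            ),
        )
        index = build_index(view)
        hits = phrase_search(index, "hematocrit abnormal", 5)
        assert [h.concept_id for h in hits] == ["A1", "B1"]

    def test_tied_candidates_sorted_by_id(self):
        view = make_view(
            make_concept("C2", "sepsis"),
            make_concept("C1", "sepsis (finding)"),
        )
        index = build_index(view)
        hits = phrase_search(index, "sepsis", 5)
        assert [h.concept_id for h in hits] == ["C1", "C2"]

    def test_no_match_returns_empty(self):
        index = build_index(make_view(make_concept("C1", "sepsis")))
        assert phrase_search(index, "quetzalcoatl", 5) == []

    def test_score_positive_iff_coverage_positive(self):
        view = generate_vocabulary(11, 30)
        index = build_index(view)
        for concept in view:
            for hit in phrase_search(index, concept.preferred_term, 30):
                assert (hit.score > 0) == (hit.coverage > 0)

    def test_unrelated_concept_preserves_relative_coverage(self):
        base = [
            make_concept("C1", "hematocrit abnormal"),
            make_concept("C2", "hematocrit"),
        ]
        small = build_index(make_view(*base))
        grown = build_index(
            make_view(*(c.copy() for c in base), make_concept("Z9", "quetzal feather"))
        )
        before = {h.concept_id: h.coverage for h in phrase_search(small, "hematocrit abnormal", 5)}
        after = {h.concept_id: h.coverage for h in phrase_search(grown, "hematocrit abnormal", 5)}
        assert {k: after[k] for k in before} == before


class TestRankingOracle:
    def test_matches_brute_force_on_random_fixtures(self, equivalences):
        """Ranking equals an exhaustive scorer on 200 random vocabularies."""
        rng = random.Random(20_240_101)
        for _ in range(200):
            n = rng.randint(5, 50)
            view = generate_vocabulary(rng.randrange(2**31), category_mix={"OTHER": n})
            index = build_index(view)
            pick = view[rng.choice(view.concept_ids)]
            scattered = " ".join(
                c.preferred_term.split()[0]
                for c in rng.sample(list(view), k=min(3, len(view)))
            )
            query = rng.choice([pick.preferred_term, scattered])
            mine = [
                (h.concept_id, h.coverage, h.score)
                for h in phrase_search(index, query, 10)
            ]
            oracle = brute_force_rank(view, query, equivalences, 10)
            assert mine == oracle, f"query={query!r}"


class TestSingleWordMatch:
    def test_each_word_finds_its_concept(self):
        view = make_view(
            make_concept("C1", "cytomegalovirus"),
            make_concept("C2", "chorioretinitis"),
        )
        index = build_index(view)
        out = single_word_match(index, {"cytomegalovirus", "chorioretinitis"})
        assert out == {"cytomegalovirus": ["C1"], "chorioretinitis": ["C2"]}

    def test_lemma_without_one_word_concept(self):
        index = build_index(make_view(make_concept("C1", "hematocrit abnormal")))
        assert single_word_match(index, {"hematocrit"}) == {"hematocrit": []}

    def test_hepatic_matches_liver_concept(self):
        index = build_index(make_view(make_concept("C1", "liver")))
        assert single_word_match(index, {"hepatic"}) == {"hepatic": ["C1"]}


class TestBatchSearch:
    def test_empty_queries(self):
        index = build_index(make_view(make_concept("C1", "sepsis")))
        assert len(batch_search(index, [])) == 0

    def test_row_blocks_follow_input_order(self):
        view = make_view(
            make_concept("C1", "sepsis"), make_concept("C2", "escherichia")
        )
        index = build_index(view)
        table = batch_search(index, [("q2", "escherichia"), ("q1", "sepsis")], k=3)
        assert list(table["code"]) == ["q2", "q1"]
        assert len(table) <= 6

    def test_identical_queries_identical_blocks(self):
        view = generate_vocabulary(9, 30)
        index = build_index(view)
        term = next(iter(view)).preferred_term
        table = batch_search(index, [("a", term), ("b", term)], k=5)
        block_a = table[table.code == "a"].drop(columns="code").reset_index(drop=True)
        block_b = table[table.code == "b"].drop(columns="code").reset_index(drop=True)
        assert block_a.equals(block_b)
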