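"""Normalization, synonym dictionary, matching primitives and the hybrid
indexing pipeline."""

import edlib
import numpy as np
import pytest
from hypothesis import given, strategies as st

from farmaner import (ConceptCatalog, IndexerConfig, NormalizationConfig,
                      SynonymDictionary, TrainingCodeMap,
                      build_synonym_dictionary, build_training_code_map,
                      index_document, index_mention, levenshtein,
                      normalize_term, suggest_candidates,
                      token_permutations)
from farmaner.indexer import NONE_CODE, spanish_plural_stripper


def dp_levenshtein(a, b):
    """Independent full-matrix dynamic program."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                          d[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
    return d[m][n]


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("Proteínas totales", "proteinas totales"),
        ("isoenzimas de FA", "isoenzimas fa"),
        ("gamma-glutamiltransferasa", "gamma glutamiltransferasa"),
        ("Antígeno cancerígeno 15-3", "antigeno cancerigeno 15 3"),
        ("beta-HCG", "beta hcg"),
        ("proteína A amiloide", "proteina a amiloide"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_term(raw) == expected

    @given(st.text(alphabet="aábcdeéfghi -./ÁÉ", max_size=25))
    def test_idempotent(self, text):
        once = normalize_term(text)
        assert normalize_term(once) == once

    def test_plural_stripper_plugin(self):
        cfg = NormalizationConfig(lemmatizer=spanish_plural_stripper)
        assert normalize_term("isoenzimas", cfg) == "isoenzima"
        assert normalize_term("dosis", cfg) == "dosis"


class TestSynonymDictionary:
    def test_union_merge_across_sources(self):
        d = build_synonym_dictionary(
            [["GGT\tGGTP"], ["GGTP\tgamma GT"]])
        assert d.group("ggt") == {"ggt", "ggtp", "gamma gt"}

    def test_ggt_fixture_group(self, fixture_resources):
        syns = fixture_resources.dictionary.synonyms("ggt")
        assert syns == {"gama glutamil transferasa", "ggtp",
                        "gamma glutamiltransferasa", "gamma gt"}

    def test_duplicates_collapse(self):
        d = build_synonym_dictionary([["A\tB"], ["A\tB"]])
        assert d.group("a") == {"a", "b"}

    def test_unknown_term_empty(self):
        assert SynonymDictionary().synonyms("nada") == set()

    def test_symmetry(self, fixture_resources):
        d = fixture_resources.dictionary
        for term in ("ggt", "ggtp", "adriamicina", "doxorrubicina"):
            for other in d.synonyms(term):
                assert term in d.synonyms(other)


class TestPermutations:
    def test_two_tokens(self):
        assert token_permutations("dimero d") == {"dimero d", "d dimero"}

    def test_three_tokens_include_reordering(self):
        perms = token_permutations("proteina a amiloide")
        assert len(perms) == 6
        assert "proteina amiloide a" in perms

    def test_single_token(self):
        assert token_permutations("ggt") == {"ggt"}

    def test_cap_on_long_terms(self):
        term = " ".join("abcdefg")
        assert token_permutations(term) == {term}


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,d", [
        ("", "abc", 3),
        ("abc", "abd", 1),
        ("antirna", "antiarina", 2),
        ("abc", "abc", 0),
    ])
    def test_examples(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_against_dp_and_edlib_oracles(self):
        rng = np.random.default_rng(42)
        alphabet = "abcdefg "
        for _ in range(2000):
            a = "".join(rng.choice(list(alphabet),
                                   size=rng.integers(0, 13)))
            b = "".join(rng.choice(list(alphabet),
                                   size=rng.integers(0, 13)))
            d = levenshtein(a, b)
            assert d == dp_levenshtein(a, b)
            if a and b:
                assert d == edlib.align(a, b)["editDistance"]

    @given(st.text(alphabet="abc", max_size=8),
           st.text(alphabet="abc", max_size=8),
           st.text(alphabet="abc", max_size=8))
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert levenshtein(a, a) == 0
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestSuggestCandidates:
    def test_nearest_description_wins(self):
        cat = ConceptCatalog([("47646004", "antiarina"),
                              ("372817009", "doxorrubicina")])
        best = suggest_candidates(cat, "antirna", k=1)
        assert best == [("47646004", "antiarina", 2)]

    def test_exact_description_first_with_zero_distance(self,
                                                        fixture_resources):
        out = suggest_candidates(fixture_resources.catalog,
                                 "doxorrubicina", k=3)
        assert out[0] == ("372817009", "doxorrubicina", 0)

    def test_k_larger_than_catalog(self, fixture_resources):
        out = suggest_candidates(fixture_resources.catalog, "x", k=100)
        assert len(out) == len(fixture_resources.catalog)
        assert [d for _, _, d in out] == sorted(d for _, _, d in out)


class TestTrainingCodeMap:
    def test_majority_wins(self):
        m = build_training_code_map([("glucosa", "1"), ("glucosa", "1"),
                                     ("glucosa", "2")])
        assert m.get("glucosa") == "1"

    def test_tie_lowest_code(self):
        m = build_training_code_map([("glucosa", "222"), ("glucosa", "111")])
        assert m.get("glucosa") == "111"

    def test_empty_input(self):
        assert len(build_training_code_map([])) == 0


class TestIndexMention:
    def test_supervised_stage_first(self, fixture_resources):
        code_map = TrainingCodeMap({"glucosa": "67079006"})
        r = index_mention("Glucosa", code_map, fixture_resources.dictionary,
                          fixture_resources.catalog)
        assert (r.code, r.stage, r.distance) == ("67079006", "supervised", 0)

    def test_exact_entity_stage(self, fixture_resources, empty_code_map):
        r = index_mention("doxorrubicina", empty_code_map,
                          fixture_resources.dictionary,
                          fixture_resources.catalog)
        assert (r.code, r.stage) == ("372817009", "exact-entity")

    def test_ggt_via_synonym(self, fixture_resources, empty_code_map):
        r = index_mention("GGT", empty_code_map,
                          fixture_resources.dictionary,
                          fixture_resources.catalog)
        assert (r.code, r.stage) == ("60153001", "exact-synonym")
        assert r.matched_description == "gamma glutamiltransferasa"

    def test_adriamicina_via_synonym(self, fixture_resources,
                                     empty_code_map):
        r = index_mention("Adriamicina", empty_code_map,
                          fixture_resources.dictionary,
                          fixture_resources.catalog)
        assert (r.code, r.stage) == ("372817009", "exact-synonym")

    def test_beta_hcg_via_fuzzy(self, fixture_resources, empty_code_map):
        r = index_mention("beta-HCG", empty_code_map,
                          fixture_resources.dictionary,
                          fixture_resources.catalog)
        assert (r.code, r.stage) == ("412126005", "fuzzy")

    def test_antirna_via_fuzzy(self, fixture_resources, empty_code_map):
        r = index_mention("antiRNA", empty_code_map,
                          fixture_resources.dictionary,
                          fixture_resources.catalog)
        assert (r.code, r.stage, r.distance) == ("47646004", "fuzzy", 2)

    def test_permutation_stage(self, empty_code_map):
        cat = ConceptCatalog([("111", "d dimero")])
        r = index_mention("dímero D", empty_code_map, SynonymDictionary(),
                          cat)
        assert (r.code, r.stage) == ("111", "exact-permutation")

    def test_supervised_precedence_property(self, fixture_resources):
        """Adding a surface to the supervised map always changes its stage
        to supervised, whatever the other resources say."""
        for surface in ("GGT", "Adriamicina", "beta-HCG", "antiRNA"):
            term = normalize_term(surface)
            code_map = TrainingCodeMap({term: "999"})
            r = index_mention(surface, code_map,
                              fixture_resources.dictionary,
                              fixture_resources.catalog)
            assert (r.code, r.stage) == ("999", "supervised")

    def test_catalog_description_resolves_at_distance_zero(
            self, fixture_resources, empty_code_map):
        for entry in fixture_resources.catalog.entries:
            r = index_mention(entry.description, empty_code_map,
                              fixture_resources.dictionary,
                              fixture_resources.catalog)
            assert r.distance == 0
            codes = {e.code for e in
                     fixture_resources.catalog.lookup_description(
                         entry.description)}
            assert r.code in codes

    def test_enlarging_dictionary_preserves_exact_matches(
            self, fixture_resources, empty_code_map):
        bigger = build_synonym_dictionary(
            [["GGT\tgama glutamil transferasa\tGGTP\t"
              "gamma-glutamiltransferasa\tgamma GT"],
             ["Adriamicina\tdoxorrubicina"],
             ["dímero D\tD dímero"],
             ["nuevo termino\totra cosa"]])
        for surface in ("GGT", "Adriamicina"):
            before = index_mention(surface, empty_code_map,
                                   fixture_resources.dictionary,
                                   fixture_resources.catalog)
            after = index_mention(surface, empty_code_map, bigger,
                                  fixture_resources.catalog)
            assert before.distance == 0
            assert after.code == before.code

    def test_empty_catalog_yields_none(self, empty_code_map):
        r = index_mention("x", empty_code_map, SynonymDictionary(),
                          ConceptCatalog([]))
        assert (r.code, r.stage) == (NONE_CODE, "none")

    def test_max_distance_cutoff(self, fixture_resources, empty_code_map):
        cfg = IndexerConfig(max_distance=1)
        r = index_mention("beta-HCG", empty_code_map,
                          fixture_resources.dictionary,
                          fixture_resources.catalog, cfg)
        assert (r.code, r.stage) == (NONE_CODE, "none")


class TestIndexDocument:
    class Mention:
        def __init__(self, surface, label="NORMALIZABLES"):
            self.surface = surface
            self.label = label
            self.start = 0
            self.end = len(surface)

    def test_codes_deduplicated(self, fixture_resources, empty_code_map):
        mentions = [self.Mention("Adriamicina"),
                    self.Mention("doxorrubicina")]
        codes, results = index_document(
            mentions, empty_code_map, fixture_resources.dictionary,
            fixture_resources.catalog)
        assert codes == {"372817009"}
        assert len(results) == 2

    def test_worked_example_pair(self, fixture_resources, empty_code_map):
        mentions = [self.Mention("GGT", "PROTEINAS"),
                    self.Mention("Adriamicina")]
        codes, _ = index_document(
            mentions, empty_code_map, fixture_resources.dictionary,
            fixture_resources.catalog)
        assert codes == {"60153001", "372817009"}

    def test_unclear_skipped(self, fixture_resources, empty_code_map):
        mentions = [self.Mention("Adriamicina", "UNCLEAR")]
        codes, results = index_document(
            mentions, empty_code_map, fixture_resources.dictionary,
            fixture_resources.catalog)
        assert codes == set() and results == []

    def test_all_none_gives_empty_set(self, empty_code_map):
        mentions = [self.Mention("x"), self.Mention("y")]
        codes, results = index_document(mentions, empty_code_map,
                                        SynonymDictionary(),
                                        ConceptCatalog([]))
        assert codes == set()
        assert all(r.code == NONE_CODE for r in results)
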