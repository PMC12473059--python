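"""Terminology normalization: preprocessing, the three matching stages,
graph consolidation, thesaurus output and validation sampling."""

import math
from difflib import SequenceMatcher

import numpy as np
import pytest

import psorimetrics as pm
from psorimetrics.normalize import (
    NormalizationConfig, SynonymPair, TermEntry, ValidationPlan,
    build_term_entries, fuzzy_pair_allowed, largest_remainder_allocation,
)


def entries(*cores, freq=1):
    return [TermEntry(raw=c, core=c, frequency=freq) for c in cores]


class TestPreprocess:
    @pytest.mark.parametrize("raw,expected", [
        ("  TNF-Alpha ", "tnf-alpha"),
        ("IL—17", "il-17"),                       # em-dash
        ("TNF-α inhibitors", "tnf-alpha inhibitors"),  # Greek alpha
        ("Secukinumab (AIN457)", "secukinumab"),
        ("  methotrexate   therapy ", "methotrexate therapy"),
    ])
    def test_examples(self, raw, expected):
        assert pm.preprocess_term(raw) == expected

    def test_empty_after_stripping_errors(self):
        with pytest.raises(ValueError):
            pm.preprocess_term(" (%) ")
        with pytest.raises(ValueError):
            pm.preprocess_term("   ")


class TestStageExact:
    def test_shared_collapse_key_links_all(self):
        pairs = pm.stage_exact(entries("tnf-alpha", "tnf alpha", "tnfalpha"))
        assert len(pairs) == 3
        assert all(p.score == 1.0 and p.stage == "exact" for p in pairs)

    def test_distinct_terms_unlinked(self):
        assert pm.stage_exact(entries("methotrexate", "secukinumab")) == []

    def test_two_planted_families(self):
        terms = entries("tnf-alpha", "tnf alpha", "tnfalpha", "il 17", "il-17", "methotrexate")
        pairs = pm.stage_exact(terms)
        by_key = {}
        for p in pairs:
            by_key.setdefault(pm.collapse_key(p.term_a), []).append(p)
        assert len(by_key["tnfalpha"]) == 3  # C(3,2)
        assert len(by_key["il17"]) == 1
        assert len(pairs) == 4


class TestEmbedding:
    def test_identical_strings_cosine_one(self):
        v = pm.embed_terms(entries("secukinumab", "secukinumab"))
        assert np.dot(v[0], v[1]) == pytest.approx(1.0)

    def test_disjoint_trigrams_cosine_zero(self):
        v = pm.embed_terms(entries("abcd", "wxyz"))
        assert np.dot(v[0], v[1]) == pytest.approx(0.0)

    def test_unit_norms(self):
        v = pm.embed_terms(entries("cyclosporine", "il-17", "x"))
        assert np.linalg.norm(v, axis=1) == pytest.approx(1.0)

    def test_trigram_overlap_oracle(self):
        # independent oracle: shared trigram count / geometric mean of set sizes
        def grams(core):
            padded = f" {core} "
            return {padded[i:i + 3] for i in range(len(padded) - 2)}

        a, b = grams("cyclosporin"), grams("cyclosporine")
        expected = len(a & b) / math.sqrt(len(a) * len(b))
        assert expected == pytest.approx(10 / math.sqrt(11 * 12))
        v = pm.embed_terms(entries("cyclosporin", "cyclosporine"))
        assert float(np.dot(v[0], v[1])) == pytest.approx(expected)

    def test_unknown_provider_falls_back(self, caplog):
        with caplog.at_level("WARNING"):
            v = pm.embed_terms(entries("a b", "a b"), provider="no-such-model")
        assert np.dot(v[0], v[1]) == pytest.approx(1.0)
        assert any("fall" in m for m in caplog.messages)


def _brute_force_dbscan_pairs(vectors, terms, threshold, min_samples):
    """Independent density-clustering oracle: neighbor graph at cosine >=
    threshold, core points have >= min_samples points (self included) in their
    neighborhood, clusters are components over core points with border points
    attached to a neighboring core's cluster."""
    n = len(terms)
    sim = vectors @ vectors.T
    neighbors = [{j for j in range(n) if sim[i, j] >= threshold - 1e-12} for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    label = [-1] * n
    cluster = 0
    for i in range(n):
        if not core[i] or label[i] >= 0:
            continue
        stack = [i]
        label[i] = cluster
        while stack:
            cur = stack.pop()
            for j in neighbors[cur]:
                if label[j] < 0:
                    label[j] = cluster
                    if core[j]:
                        stack.append(j)
        cluster += 1
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if label[i] >= 0 and label[i] == label[j]:
                pairs.add(tuple(sorted((terms[i].core, terms[j].core))))
    return pairs


class TestStageSemantic:
    def test_identical_vectors_pair(self):
        terms = entries("tnf-alpha", "tnf-alpha 2")
        v = np.array([[1.0, 0.0], [1.0, 0.0]])
        pairs = pm.stage_semantic(v, terms, NormalizationConfig())
        assert len(pairs) == 1 and pairs[0].score == pytest.approx(1.0)

    def test_orthogonal_vectors_no_pairs(self):
        terms = entries("a", "b", "c")
        v = np.eye(3)
        assert pm.stage_semantic(v, terms, NormalizationConfig()) == []

    def test_matches_brute_force_oracle(self):
        terms = entries("cyclosporin", "cyclosporine", "cyclosporins",
                        "methotrexate", "methotrexates", "secukinumab",
                        "infliximab", "etanercept", "tnf-alpha", "tnf-alphas")
        cfg = NormalizationConfig()
        v = pm.embed_terms(terms)
        got = {tuple(sorted((p.term_a, p.term_b)))
               for p in pm.stage_semantic(v, terms, cfg)}
        expected = _brute_force_dbscan_pairs(
            v, terms, cfg.semantic_similarity_threshold, cfg.semantic_min_neighbors)
        assert got == expected


from hypothesis import given, settings
from hypothesis import strategies as st

_token = st.sampled_from(["methotrexate", "therapy", "psoriasis", "safety",
                          "topical", "dose", "trial"])


class TestStageFuzzy:
    def test_token_permutation_scores_one(self):
        assert pm.token_set_similarity("methotrexate therapy",
                                       "therapy methotrexate") == pytest.approx(1.0)

    @given(st.lists(_token, min_size=1, max_size=5, unique=True))
    @settings(deadline=None, derandomize=True)
    def test_permutation_invariance_property(self, tokens):
        a = " ".join(tokens)
        b = " ".join(reversed(tokens))
        assert pm.token_set_similarity(a, b) == pytest.approx(1.0)
        # subset terms also score 1 under the token-set construction
        assert pm.token_set_similarity(a, tokens[0]) == pytest.approx(1.0)

    def test_distinct_inn_stems_rejected(self):
        assert not fuzzy_pair_allowed("infliximab", "ixekizumab")
        cfg = NormalizationConfig()
        pairs = pm.stage_fuzzy(entries("infliximab", "ixekizumab"), cfg)
        assert pairs == []

    def test_drug_never_pairs_with_non_drug(self):
        assert not fuzzy_pair_allowed("etanercept", "methotrexate")

    def test_curated_drug_list_matches_hand_enumeration(self):
        terms = entries(
            "infliximab", "infliximab biosimilar", "ixekizumab",
            "methotrexate therapy", "therapy methotrexate", "methotrexate",
            "etanercept", "secukinumab safety",
        )
        pairs = pm.stage_fuzzy(terms, NormalizationConfig())
        got = {tuple(sorted((p.term_a, p.term_b))) for p in pairs}
        # hand enumeration over all 28 pairs under both domain rules:
        expected = {
            ("infliximab", "infliximab biosimilar"),       # subset tokens, same stem
            ("methotrexate therapy", "therapy methotrexate"),
            ("methotrexate", "methotrexate therapy"),
            ("methotrexate", "therapy methotrexate"),
        }
        assert got == expected

    def test_scores_within_unit_interval(self):
        pairs = pm.stage_fuzzy(entries("cyclosporin", "cyclosporine"), NormalizationConfig())
        assert pairs and 0.9 <= pairs[0].score <= 1.0


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


class TestMergeGroups:
    def test_transitive_closure(self):
        pairs = [SynonymPair("a", "b", "exact", 1.0), SynonymPair("b", "c", "exact", 1.0),
                 SynonymPair("d", "e", "exact", 1.0)]
        freqs = {t: 1 for t in "abcde"}
        groups = pm.merge_groups(pairs, freqs)
        assert sorted(sorted(g.variants) for g in groups) == [["a", "b", "c"], ["d", "e"]]

    def test_min_group_size_discards_small(self):
        pairs = [SynonymPair("a", "b", "exact", 1.0), SynonymPair("b", "c", "exact", 1.0),
                 SynonymPair("d", "e", "exact", 1.0)]
        freqs = {t: 1 for t in "abcde"}
        groups = pm.merge_groups(pairs, freqs, NormalizationConfig(min_group_size=3))
        assert [sorted(g.variants) for g in groups] == [["a", "b", "c"]]

    def test_matches_union_find_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        nodes = [f"t{i}" for i in range(20)]
        pairs = []
        for _ in range(50):
            i, j = rng.choice(20, size=2, replace=False)
            pairs.append(SynonymPair(nodes[i], nodes[j], "exact", 1.0))
        freqs = {n: 1 for n in nodes}
        groups = pm.merge_groups(pairs, freqs)
        uf = _UnionFind()
        for p in pairs:
            uf.union(p.term_a, p.term_b)
        roots = {}
        for p in pairs:
            for t in (p.term_a, p.term_b):
                roots.setdefault(uf.find(t), set()).add(t)
        expected = sorted(sorted(c) for c in roots.values() if len(c) >= 2)
        assert sorted(sorted(g.variants) for g in groups) == expected


class TestSelectCanonical:
    def test_highest_frequency_wins(self):
        assert pm.select_canonical({"a", "b"}, {"a": 10, "b": 3}) == "a"

    def test_tie_breaks_to_shortest(self):
        assert pm.select_canonical({"xx", "yyy"}, {"xx": 5, "yyy": 5}) == "xx"

    def test_remaining_tie_lexicographic(self):
        assert pm.select_canonical({"ppp", "qqq", "rrr"}, {"ppp": 4, "qqq": 4, "rrr": 4}) == "ppp"


class TestThesaurus:
    def test_apply_collapses_duplicates(self):
        groups = pm.merge_groups(
            [SynonymPair("tnf alpha", "tnf-alpha", "exact", 1.0)],
            {"tnf-alpha": 5, "tnf alpha": 2})
        thes = pm.build_thesaurus(groups)
        rec = pm.BiblioRecord(author_keywords=["TNF alpha", "tnf-alpha"], pub_year=2000)
        out = pm.apply_thesaurus([rec], thes)[0]
        assert out.author_keywords == ["tnf-alpha"]

    def test_unmapped_keyword_keeps_core_form(self):
        rec = pm.BiblioRecord(author_keywords=["  Methotrexate "], pub_year=2000)
        out = pm.apply_thesaurus([rec], pm.Thesaurus())[0]
        assert out.author_keywords == ["methotrexate"]

    def test_write_csv_dialect(self):
        groups = pm.merge_groups(
            [SynonymPair("tnf alpha", "tnf-alpha", "exact", 1.0)],
            {"tnf-alpha": 5, "tnf alpha": 2})
        text = pm.write_thesaurus(groups, "csv")
        assert text == "label,replace by\ntnf alpha,tnf-alpha\n"

    def test_empty_groups_header_only(self):
        assert pm.write_thesaurus([], "vosviewer-tab") == "label\treplace by\n"

    def test_write_parse_round_trip(self, normalized):
        for dialect in ("vosviewer-tab", "csv"):
            text = pm.write_thesaurus(normalized.groups, dialect)
            assert pm.parse_thesaurus(text, dialect).mapping == normalized.thesaurus.mapping


class TestPipelineProperties:
    def test_idempotent_on_normalized_corpus(self, normalized):
        again = pm.normalize_corpus(normalized.records)
        assert again.records == normalized.records

    def test_exact_pairs_survive_into_groups(self, normalized):
        membership = {}
        for g in normalized.groups:
            for v in g.variants:
                membership[v] = g.canonical
        for p in normalized.pairs:
            if p.stage == "exact":
                assert membership.get(p.term_a) == membership.get(p.term_b) is not None

    def test_inn_stem_rule_preserved_through_merging(self):
        # curated vocabulary of biologics plus formatting variants
        drugs = ["infliximab", "ixekizumab", "secukinumab", "ustekinumab",
                 "etanercept", "tofacitinib", "guselkumab", "risankizumab"]
        records = []
        for i, d in enumerate(drugs):
            for surface in (d, d.upper(), f"  {d} "):
                records.append(pm.BiblioRecord(record_id=f"r{i}{surface!r}",
                                               author_keywords=[surface], pub_year=2020))
        result = pm.normalize_corpus(records)
        from psorimetrics.normalize import _drug_token
        for g in result.groups:
            stems = {_drug_token(v)[:4] for v in g.variants if _drug_token(v)}
            assert len(stems) <= 1


class TestValidationSampling:
    def _pairs(self, n, stage):
        return [SynonymPair(f"{stage}{i}", f"{stage}{i}b", stage, 1.0) for i in range(n)]

    def test_returns_all_when_sample_exceeds_pool(self):
        pairs = self._pairs(10, "exact")
        out = pm.sample_validation_pairs(pairs, ValidationPlan(sample_size=300, seed=1))
        assert out == pairs

    def test_largest_remainder_allocation(self):
        assert largest_remainder_allocation([60, 30, 10], 10) == [6, 3, 1]
        assert largest_remainder_allocation([7, 7, 7], 10) == [4, 3, 3]
        assert sum(largest_remainder_allocation([13, 11, 5], 17)) == 17

    def test_proportional_by_stage(self):
        pairs = self._pairs(60, "exact") + self._pairs(30, "fuzzy") + self._pairs(10, "semantic")
        out = pm.sample_validation_pairs(pairs, ValidationPlan(sample_size=10, seed=5))
        counts = {s: sum(1 for p in out if p.stage == s) for s in ("exact", "fuzzy", "semantic")}
        assert counts == {"exact": 6, "fuzzy": 3, "semantic": 1}

    def test_seeded_reproducibility(self):
        pairs = self._pairs(100, "exact") + self._pairs(50, "fuzzy")
        plan = ValidationPlan(sample_size=30, seed=11)
        assert pm.sample_validation_pairs(pairs, plan) == pm.sample_validation_pairs(pairs, plan)

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            pm.sample_validation_pairs([], ValidationPlan())


class TestAgreementRate:
    def test_285_of_300_passes(self):
        votes = [[True] * 3] * 285 + [[True, True, False]] * 15
        rate, passed = pm.agreement_rate(votes, ValidationPlan())
        assert rate == pytest.approx(0.95)
        assert passed

    def test_269_of_300_fails(self):
        votes = [[True] * 3] * 269 + [[False] * 3] * 31
        rate, passed = pm.agreement_rate(votes, ValidationPlan())
        assert rate == pytest.approx(269 / 300)
        assert not passed

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pm.agreement_rate([], ValidationPlan())

    def test_missing_votes_error(self):
        with pytest.raises(ValueError):
            pm.agreement_rate([[True, True]], ValidationPlan())
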