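"""Citation/productivity indicators against brute-force oracles and the
printed-table worked examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import psorimetrics as pm
from psorimetrics.records import BiblioRecord


def brute_h(citations):
    return max((h for h in range(len(citations) + 1)
                if sum(1 for c in citations if c >= h) >= h), default=0)


def brute_g(citations):
    ranked = sorted(citations, reverse=True)
    return max((g for g in range(len(ranked) + 1)
                if sum(ranked[:g]) >= g * g), default=0)


class TestIndices:
    @pytest.mark.parametrize("citations,expected_h", [
        ([], 0), ([10, 8, 5, 4, 3], 4), ([3, 3, 3], 3), ([0, 0], 0),
    ])
    def test_h_examples(self, citations, expected_h):
        assert pm.h_index(citations) == expected_h == brute_h(citations)

    @pytest.mark.parametrize("citations,expected_g", [
        ([], 0), ([10, 8, 5, 4, 3], 5), ([1, 1, 1], 1),
    ])
    def test_g_examples(self, citations, expected_g):
        assert pm.g_index(citations) == expected_g == brute_g(citations)

    @given(st.lists(st.integers(min_value=0, max_value=500), max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_h_g_property(self, citations):
        assert pm.h_index(citations) == brute_h(citations)
        assert pm.g_index(citations) == brute_g(citations)
        assert pm.g_index(citations) >= pm.h_index(citations)

    def test_h_g_match_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(0, 51))
            citations = rng.negative_binomial(1, 0.05, size=n).tolist()
            assert pm.h_index(citations) == brute_h(citations)
            assert pm.g_index(citations) == brute_g(citations)
            assert pm.g_index(citations) >= pm.h_index(citations)


class TestAgeScaledRatios:
    def test_m_index_printed_rows(self):
        # leading dermatology journal: h=105 since 1980, census 2025
        assert pm.m_index(105, 1980, 2025) == 2.283
        # recent high-momentum journal: h=41 since 2013
        assert pm.m_index(41, 2013, 2025) == 3.154
        assert pm.m_index(0, 2000, 2025) == 0.0

    def test_tc_per_year_printed_rows(self):
        assert pm.tc_per_year(1613, 2014, 2025) == 134.42
        assert pm.tc_per_year(1402, 2021, 2025) == 280.40
        assert pm.tc_per_year(0, 2020, 2025) == 0.0

    def test_monotone_nonincreasing_in_ref_year(self):
        for ref in range(2014, 2030):
            assert pm.tc_per_year(1000, 2014, ref) >= pm.tc_per_year(1000, 2014, ref + 1)
            assert pm.m_index(50, 2000, ref) >= pm.m_index(50, 2000, ref + 1)

    def test_invalid_ref_year(self):
        with pytest.raises(ValueError):
            pm.tc_per_year(10, 2020, 2019)


class TestNormalizedTc:
    def test_examples(self):
        assert pm.normalized_tc(10, 5) == 2.0
        assert pm.normalized_tc(7, 7) == 1.0       # sole document of its year
        assert pm.normalized_tc(6, (2 + 4 + 6) / 3) == 1.5
        assert pm.normalized_tc(5, 0) == 0.0


class TestAvgCitations:
    def test_printed_country_rows(self):
        assert pm.avg_citations_per_doc(300_339, 5959) == 50.40
        assert pm.avg_citations_per_doc(93_416, 1491) == 62.65
        assert pm.avg_citations_per_doc(0, 10) == 0.0

    def test_zero_docs_errors(self):
        with pytest.raises(ValueError):
            pm.avg_citations_per_doc(5, 0)


def _rec(year, tc=0, countries=(), source=""):
    return BiblioRecord(pub_year=year, times_cited=tc,
                        countries=list(countries), source=source)


class TestYearSeries:
    def test_counts_and_means(self):
        records = [_rec(2020, 1), _rec(2020, 2), _rec(2020, 3)]
        assert pm.yearly_counts(records).to_dict() == {2020: 3}
        assert pm.yearly_mean_tc(records).to_dict() == {2020: 2.0}

    def test_empty_corpus(self):
        assert pm.yearly_counts([]).empty
        assert pm.yearly_mean_tc([]).empty

    def test_counts_equal_generator_schedule(self, corpus_and_truth):
        records, truth = corpus_and_truth
        assert pm.yearly_counts(records).to_dict() == truth.schedule


class TestCumulativeMatrix:
    def test_single_country_carries_forward(self):
        new, cum = pm.cumulative_matrix([_rec(1975, countries=["USA"]),
                                         _rec(1977, countries=["USA"])])
        assert cum.loc[1975, "USA"] == 1
        assert cum.loc[1976, "USA"] == 1
        assert cum.loc[1977, "USA"] == 2

    def test_full_counting_credits_every_country(self):
        new, _ = pm.cumulative_matrix([_rec(2000, countries=["USA", "Canada"])])
        assert new.loc[2000, "USA"] == 1 and new.loc[2000, "Canada"] == 1

    def test_final_column_equals_totals(self, corpus_and_truth):
        records, _ = corpus_and_truth
        subset = records[:200]
        _, cum = pm.cumulative_matrix(subset, "country")
        totals = {}
        for rec in subset:
            for c in rec.countries:
                totals[c] = totals.get(c, 0) + 1
        assert cum.iloc[-1].to_dict() == totals


class TestShareOfParent:
    def test_printed_peak_share(self):
        share = pm.share_of_parent(pd.Series({2022: 507}), pd.Series({2022: 1000}))
        assert share.loc[2022] == pytest.approx(50.7)

    def test_full_share(self):
        share = pm.share_of_parent(pd.Series({2000: 5}), pd.Series({2000: 5}))
        assert share.loc[2000] == pytest.approx(100.0)

    def test_sub_exceeding_parent_errors(self):
        with pytest.raises(ValueError):
            pm.share_of_parent(pd.Series({2000: 6}), pd.Series({2000: 5}))

    def test_nested_synthetic_ratio(self, corpus_and_truth):
        records, _ = corpus_and_truth
        sub = [r for r in records if "psoriasis" in r.keywords()]
        share = pm.share_of_parent(pm.yearly_counts(sub), pm.yearly_counts(records))
        for year in share.index:
            by_hand = 100.0 * sum(1 for r in sub if r.pub_year == year) \
                / sum(1 for r in records if r.pub_year == year)
            assert share.loc[year] == pytest.approx(by_hand)


class TestEntityTables:
    def test_journal_metrics_invariants(self, corpus_and_truth):
        records, _ = corpus_and_truth
        for jm in pm.journal_metrics(records):
            assert jm.g_index >= jm.h_index
            assert jm.h_index <= jm.n_publications
            assert jm.m_index >= 0

    def test_country_stats_full_vs_fractional(self, corpus_and_truth):
        records, _ = corpus_and_truth
        full = {c.country: c.documents for c in pm.country_stats(records, "full")}
        frac = {c.country: c.documents for c in pm.country_stats(records, "fractional")}
        for country, n_full in full.items():
            assert n_full >= frac[country] - 1e-9

    def test_top_cited_table_normalization(self, corpus_and_truth):
        records, _ = corpus_and_truth
        table = pm.top_cited_table(records, top_n=5)
        assert len(table) == 5
        assert (table["tc"].values == sorted(table["tc"].values)[::-1]).all()
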