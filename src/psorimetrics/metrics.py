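"""Citation and productivity indicators.

Implements the standard bibliometric index family (Hirsch h, Egghe g,
m-quotient), document-level citation rates (TC/year, year-normalized TC),
per-entity aggregates (per-journal index tables, per-country document and
citation totals) and temporal series (annual output, mean citations per
article, cumulative entity matrices, share-of-parent-corpus percentages).

Conventions, chosen to be self-consistent with inclusive year counting:
age-dependent denominators count years inclusively (``ref_year - year + 1``)
and all printed ratios use round-half-up at the stated precision (2 decimals
for ratios, 3 for the m-index).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .records import BiblioRecord


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (``2.2826…`` → ``2.283`` at 3 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsConfig:
    """Reference year and rounding for age-dependent indices.

    ``ref_year`` defaults to the corpus's maximum publication year; the census
    year of an external table can be supplied explicitly.
    """

    ref_year: int | None = None
    ratio_decimals: int = 2
    m_index_decimals: int = 3

    def resolve_ref_year(self, records: list[BiblioRecord]) -> int:
        if self.ref_year is not None:
            return self.ref_year
        if not records:
            raise ValueError("empty corpus and no explicit ref_year")
        return max(r.pub_year for r in records)


@dataclass
class JournalMetrics:
    source: str
    h_index: int
    g_index: int
    m_index: float
    total_citations: int
    n_publications: int
    start_year: int


@dataclass
class CountryStats:
    country: str
    documents: float
    citations: int
    avg_citations_per_doc: float
    tls: float = 0.0


# ---------------------------------------------------------------------------
# Core indices
# ---------------------------------------------------------------------------

def h_index(citations: list[int]) -> int:
    """Largest h such that at least h papers have >= h citations each."""
    ranked = sorted(citations, reverse=True)
    h = 0
    for i, c in enumerate(ranked, start=1):
        if c >= i:
            h = i
        else:
            break
    return h


def g_index(citations: list[int]) -> int:
    """Largest g <= n such that the top g papers together have >= g² citations."""
    ranked = sorted(citations, reverse=True)
    total = 0
    g = 0
    for i, c in enumerate(ranked, start=1):
        total += c
        if total >= i * i:
            g = i
    return g


def m_index(h: int, start_year: int, ref_year: int, decimals: int = 3) -> float:
    """m-quotient: h divided by the inclusive number of publishing years."""
    if ref_year < start_year:
        raise ValueError("ref_year precedes start_year")
    return round_half_up(h / (ref_year - start_year + 1), decimals)


def tc_per_year(tc: int, pub_year: int, ref_year: int, decimals: int = 2) -> float:
    """Citations per inclusive year of document age."""
    if ref_year < pub_year:
        raise ValueError("ref_year precedes pub_year")
    return round_half_up(tc / (ref_year - pub_year + 1), decimals)


def normalized_tc(tc: int, year_mean_tc: float, decimals: int = 2) -> float:
    """Citations relative to the mean of same-year documents (0 if mean is 0)."""
    if year_mean_tc < 0:
        raise ValueError("negative year mean")
    if year_mean_tc == 0:
        return 0.0
    return round_half_up(tc / year_mean_tc, decimals)


def avg_citations_per_doc(total_citations: int, n_docs: int, decimals: int = 2) -> float:
    if n_docs <= 0:
        raise ValueError("n_docs must be positive")
    return round_half_up(total_citations / n_docs, decimals)


# ---------------------------------------------------------------------------
# Temporal series
# ---------------------------------------------------------------------------

def yearly_counts(records: list[BiblioRecord]) -> pd.Series:
    """Documents per publication year (years with no documents omitted)."""
    years = pd.Series([r.pub_year for r in records], dtype=int)
    if years.empty:
        return pd.Series(dtype=int)
    return years.value_counts().sort_index()


def yearly_mean_tc(records: list[BiblioRecord]) -> pd.Series:
    """Arithmetic mean of times-cited per publication year."""
    if not records:
        return pd.Series(dtype=float)
    df = pd.DataFrame({"year": [r.pub_year for r in records],
                       "tc": [r.times_cited for r in records]})
    return df.groupby("year")["tc"].mean().sort_index()


def share_of_parent(sub_counts: pd.Series, parent_counts: pd.Series) -> pd.Series:
    """Percentage share of a sub-corpus within its parent, per year.

    Years with a zero or missing parent count are omitted; a sub count
    exceeding its parent is an error.
    """
    shared = sub_counts.index.intersection(parent_counts.index)
    out = {}
    for year in shared:
        parent = parent_counts.loc[year]
        if parent == 0:
            continue
        sub = sub_counts.loc[year]
        if sub > parent:
            raise ValueError(f"sub-corpus exceeds parent in {year}: {sub} > {parent}")
        out[year] = 100.0 * sub / parent
    return pd.Series(out, dtype=float).sort_index()


def _entity_values(rec: BiblioRecord, entity_field: str) -> list[str]:
    if entity_field == "country":
        return list(rec.countries)
    if entity_field == "source":
        return [rec.source] if rec.source else []
    if entity_field == "institution":
        # first comma token of each affiliation, deduplicated
        seen, out = set(), []
        for aff in rec.affiliations:
            inst = aff.split(",", 1)[0].strip()
            if inst and inst not in seen:
                seen.add(inst)
                out.append(inst)
        return out
    raise ValueError(f"unknown entity field: {entity_field!r}")


def cumulative_matrix(records: list[BiblioRecord], entity_field: str = "country") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year new-publication and running-total matrices (year × entity).

    Multi-entity records credit every listed entity (full counting). Returns
    ``(new, cumulative)`` DataFrames over the contiguous corpus year span.
    """
    rows = []
    for rec in records:
        for entity in _entity_values(rec, entity_field):
            rows.append((rec.pub_year, entity))
    if not rows:
        empty = pd.DataFrame(dtype=int)
        return empty, empty
    df = pd.DataFrame(rows, columns=["year", "entity"])
    new = df.groupby(["year", "entity"]).size().unstack(fill_value=0)
    full_years = range(int(new.index.min()), int(new.index.max()) + 1)
    new = new.reindex(full_years, fill_value=0)
    new = new[sorted(new.columns)]
    return new, new.cumsum()


# ---------------------------------------------------------------------------
# Per-entity tables
# ---------------------------------------------------------------------------

def journal_metrics(records: list[BiblioRecord], config: MetricsConfig | None = None) -> list[JournalMetrics]:
    """Per-journal h/g/m-index table over the corpus, sorted by h descending."""
    config = config or MetricsConfig()
    ref = config.resolve_ref_year(records)
    by_source: dict[str, list[BiblioRecord]] = {}
    for rec in records:
        if rec.source:
            by_source.setdefault(rec.source, []).append(rec)
    out = []
    for source in sorted(by_source):
        recs = by_source[source]
        citations = [r.times_cited for r in recs]
        h = h_index(citations)
        start = min(r.pub_year for r in recs)
        out.append(JournalMetrics(
            source=source,
            h_index=h,
            g_index=g_index(citations),
            m_index=m_index(h, start, ref, config.m_index_decimals),
            total_citations=sum(citations),
            n_publications=len(recs),
            start_year=start,
        ))
    out.sort(key=lambda jm: (-jm.h_index, -jm.total_citations, jm.source))
    return out


def country_stats(records: list[BiblioRecord], counting: str = "full",
                  config: MetricsConfig | None = None) -> list[CountryStats]:
    """Per-country document and citation aggregates.

    ``counting="full"`` credits each listed country a whole document (and the
    record's full TC); ``"fractional"`` credits 1/k of a document to each of a
    record's k countries (citations scaled likewise). Sorted by documents
    descending.
    """
    if counting not in {"full", "fractional"}:
        raise ValueError(f"unknown counting mode: {counting!r}")
    docs: dict[str, float] = {}
    cites: dict[str, float] = {}
    for rec in records:
        countries = rec.countries
        if not countries:
            continue
        credit = 1.0 if counting == "full" else 1.0 / len(countries)
        for c in countries:
            docs[c] = docs.get(c, 0.0) + credit
            cites[c] = cites.get(c, 0.0) + rec.times_cited * credit
    out = []
    for c in sorted(docs):
        n = docs[c]
        out.append(CountryStats(
            country=c,
            documents=n if counting == "fractional" else int(n),
            citations=int(round(cites[c])),
            avg_citations_per_doc=round_half_up(cites[c] / n, 2) if n else 0.0,
        ))
    out.sort(key=lambda cs: (-cs.documents, cs.country))
    return out


def top_cited_table(records: list[BiblioRecord], top_n: int = 10,
                    config: MetricsConfig | None = None) -> pd.DataFrame:
    """Most-cited documents with TC, TC/year and year-normalized TC columns."""
    config = config or MetricsConfig()
    if not records:
        return pd.DataFrame(columns=["record_id", "tc", "tc_per_year", "normalized_tc"])
    ref = config.resolve_ref_year(records)
    means = yearly_mean_tc(records)
    ranked = sorted(records, key=lambda r: (-r.times_cited, r.record_id))[:top_n]
    rows = [{
        "record_id": r.record_id,
        "pub_year": r.pub_year,
        "tc": r.times_cited,
        "tc_per_year": tc_per_year(r.times_cited, r.pub_year, ref),
        "normalized_tc": normalized_tc(r.times_cited, float(means.loc[r.pub_year])),
    } for r in ranked]
    return pd.DataFrame(rows)
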