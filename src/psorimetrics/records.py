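"""Record model for bibliographic corpora.

A :class:`BiblioRecord` is the pipeline's in-memory representation of one
publication as exported from the Web of Science Core Collection: the fields
every downstream stage consumes (publication year, document type, language,
author keywords, Keywords Plus, affiliations, times cited) plus a ``raw_fields``
map that preserves any export tag the parser does not model, so that parse →
write → parse is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable


@dataclass
class BiblioRecord:
    """One publication record.

    Attributes
    ----------
    record_id:
        Opaque identifier (WoS ``UT`` accession when present, else synthetic).
    title, authors, source:
        Bibliographic front matter; ``source`` is the journal name (``SO``).
    pub_year:
        Publication year (``PY``).
    doc_type, language:
        Controlled vocabulary strings (``DT``, ``LA``).
    author_keywords, keywords_plus:
        Author-supplied (``DE``) and database-assigned (``ID``) keyword lists.
    affiliations:
        Raw ``C1`` address strings.
    countries:
        Standardized country names derived from affiliations, deduplicated in
        order of first appearance.
    times_cited:
        Total citation count (``TC``), 0 when absent.
    doi:
        Digital object identifier (``DI``) or empty string.
    raw_fields:
        Unmodelled export tags, preserved verbatim for round-tripping.
    """

    record_id: str = ""
    title: str = ""
    authors: list[str] = field(default_factory=list)
    source: str = ""
    pub_year: int = 0
    doc_type: str = ""
    language: str = ""
    author_keywords: list[str] = field(default_factory=list)
    keywords_plus: list[str] = field(default_factory=list)
    affiliations: list[str] = field(default_factory=list)
    countries: list[str] = field(default_factory=list)
    times_cited: int = 0
    doi: str = ""
    raw_fields: dict[str, str] = field(default_factory=dict)

    def keywords(self, source: str = "union") -> list[str]:
        """Keyword list used by the analysis stages.

        ``source`` is one of ``"author"`` (DE), ``"plus"`` (ID) or ``"union"``
        (DE followed by unseen ID terms, the default throughout the pipeline).
        """
        if source == "author":
            return list(self.author_keywords)
        if source == "plus":
            return list(self.keywords_plus)
        if source == "union":
            seen: set[str] = set()
            out: list[str] = []
            for kw in list(self.author_keywords) + list(self.keywords_plus):
                if kw not in seen:
                    seen.add(kw)
                    out.append(kw)
            return out
        raise ValueError(f"unknown keyword source: {source!r}")

    def copy(self, **changes) -> "BiblioRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class CorpusFilter:
    """Inclusion criteria applied to a parsed corpus.

    Defaults mirror the study design for the psoriasis pharmacotherapy corpus:
    articles and reviews, published in English, 1975-2025 inclusive.
    """

    allowed_doc_types: frozenset[str] = frozenset({"Article", "Review"})
    allowed_languages: frozenset[str] = frozenset({"English"})
    year_range: tuple[int, int] = (1975, 2025)

    def __post_init__(self):
        if not self.allowed_doc_types or not self.allowed_languages:
            raise ValueError("allowed_doc_types and allowed_languages must be non-empty")
        lo, hi = self.year_range
        if lo > hi:
            raise ValueError(f"year_range min {lo} exceeds max {hi}")

    def matches(self, rec: BiblioRecord) -> bool:
        lo, hi = self.year_range
        return (
            rec.doc_type.lower() in {t.lower() for t in self.allowed_doc_types}
            and rec.language.lower() in {l.lower() for l in self.allowed_languages}
            and lo <= rec.pub_year <= hi
        )


def iter_keywords(records: Iterable[BiblioRecord], source: str = "union"):
    """Yield ``(record, keyword)`` pairs over a corpus."""
    for rec in records:
        for kw in rec.keywords(source):
            yield rec, kw
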