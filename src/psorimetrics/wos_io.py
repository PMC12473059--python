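"""Reading, filtering, deduplicating and writing WoS-style bibliographic exports.

Two export dialects are supported, selected explicitly:

``plain``
    The classic field-tagged format: a ``FN``/``VR`` preamble, one ``PT`` …
    ``ER`` block per record, two-letter tags in columns 1-2, continuation
    lines indented three spaces, terminated by ``EF``.
``tab``
    The tab-delimited variant: one header row of tag names, one row per
    record, multi-valued fields ``;``-joined.

Both dialects round-trip through :func:`parse_wos_export` /
:func:`write_wos_export` without loss on the record model.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from importlib import resources

from .records import BiblioRecord, CorpusFilter

log = logging.getLogger(__name__)

# Tags the record model understands; anything else lands in raw_fields.
_KNOWN_TAGS = {"PT", "AU", "TI", "SO", "DE", "ID", "C1", "TC", "PY", "DI", "LA", "DT", "UT", "ER"}

_MULTILINE_TAGS = {"AU", "C1"}  # one value per line in the plain dialect

_TAB_COLUMNS = ["UT", "PT", "AU", "TI", "SO", "DE", "ID", "C1", "TC", "PY", "DI", "LA", "DT"]


class WosParseError(ValueError):
    """Raised when an export file is structurally malformed."""


def _split_list(value: str) -> list[str]:
    return [part.strip() for part in value.split(";") if part.strip()]


def _block_to_record(fields: dict[str, list[str]], index: int) -> BiblioRecord | None:
    """Convert a tag→values map for one record block into a BiblioRecord.

    Returns None (with a logged warning) when PY is unparseable.
    """
    def first(tag: str) -> str:
        vals = fields.get(tag, [])
        return vals[0] if vals else ""

    py_raw = first("PY").strip()
    try:
        pub_year = int(py_raw)
    except ValueError:
        log.warning("record %d skipped: unparseable PY %r", index, py_raw)
        return None

    tc_raw = first("TC").strip()
    try:
        times_cited = max(0, int(tc_raw)) if tc_raw else 0
    except ValueError:
        times_cited = 0

    raw_fields = {
        tag: "; ".join(vals)
        for tag, vals in fields.items()
        if tag not in _KNOWN_TAGS
    }

    affiliations = fields.get("C1", [])
    rec = BiblioRecord(
        record_id=first("UT") or f"rec-{index:06d}",
        title=first("TI"),
        authors=fields.get("AU", []),
        source=first("SO"),
        pub_year=pub_year,
        doc_type=first("DT"),
        language=first("LA"),
        author_keywords=_split_list(first("DE")),
        keywords_plus=_split_list(first("ID")),
        affiliations=list(affiliations),
        countries=extract_countries(affiliations),
        times_cited=times_cited,
        doi=first("DI"),
        raw_fields=raw_fields,
    )
    return rec


def _parse_plain(text: str) -> list[BiblioRecord]:
    records: list[BiblioRecord] = []
    fields: dict[str, list[str]] = {}
    in_record = False
    current_tag = ""
    index = 0
    for line in text.splitlines():
        if not in_record:
            if line.startswith("PT "):
                in_record = True
                fields = {"PT": [line[3:].strip()]}
                current_tag = "PT"
            continue
        if line.startswith("ER"):
            rec = _block_to_record(fields, index)
            if rec is not None:
                records.append(rec)
            index += 1
            in_record = False
            continue
        if line.startswith("   "):  # continuation of the current tag
            value = line[3:].rstrip()
            if current_tag in _MULTILINE_TAGS:
                fields.setdefault(current_tag, []).append(value.strip())
            elif current_tag:
                prev = fields[current_tag]
                prev[-1] = (prev[-1] + " " + value.strip()).strip()
            continue
        m = re.match(r"^([A-Z][A-Z0-9]) (.*)$", line)
        if m:
            current_tag, value = m.group(1), m.group(2).rstrip()
            fields.setdefault(current_tag, []).append(value.strip())
    if in_record:
        raise WosParseError(f"record {index} missing terminating ER tag")
    return records


def _parse_tab(text: str) -> list[BiblioRecord]:
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows = list(reader)
    if not rows:
        raise WosParseError("tab export has no header row")
    header = [h.strip() for h in rows[0]]
    records: list[BiblioRecord] = []
    for index, row in enumerate(rows[1:]):
        if not any(cell.strip() for cell in row):
            continue
        fields: dict[str, list[str]] = {}
        for tag, cell in zip(header, row):
            cell = cell.strip()
            if not cell:
                continue
            if tag in _MULTILINE_TAGS:
                fields[tag] = _split_list(cell)
            else:
                fields[tag] = [cell]
        rec = _block_to_record(fields, index)
        if rec is not None:
            records.append(rec)
    return records


def parse_wos_export(text: str, dialect: str = "plain") -> list[BiblioRecord]:
    """Parse an export into records, one per ``PT``…``ER`` block or row.

    Missing ``TC`` parses as 0; a record with unparseable ``PY`` is skipped
    with a logged warning; a block missing its terminating ``ER`` raises
    :class:`WosParseError` naming the record index.
    """
    if not text.strip():
        raise WosParseError("empty export text")
    if dialect == "plain":
        return _parse_plain(text)
    if dialect == "tab":
        return _parse_tab(text)
    raise ValueError(f"unsupported dialect: {dialect!r}")


def _record_fields(rec: BiblioRecord) -> list[tuple[str, str | list[str]]]:
    out: list[tuple[str, str | list[str]]] = [("PT", "J")]
    if rec.authors:
        out.append(("AU", rec.authors))
    if rec.title:
        out.append(("TI", rec.title))
    if rec.source:
        out.append(("SO", rec.source))
    if rec.language:
        out.append(("LA", rec.language))
    if rec.doc_type:
        out.append(("DT", rec.doc_type))
    if rec.author_keywords:
        out.append(("DE", "; ".join(rec.author_keywords)))
    if rec.keywords_plus:
        out.append(("ID", "; ".join(rec.keywords_plus)))
    if rec.affiliations:
        out.append(("C1", rec.affiliations))
    for tag, value in sorted(rec.raw_fields.items()):
        out.append((tag, value))
    out.append(("TC", str(rec.times_cited)))
    if rec.doi:
        out.append(("DI", rec.doi))
    out.append(("PY", str(rec.pub_year)))
    out.append(("UT", rec.record_id))
    return out


def write_wos_export(records: list[BiblioRecord], dialect: str = "plain") -> str:
    """Serialize records back into an export of the given dialect."""
    if dialect == "plain":
        lines = ["FN psorimetrics synthetic export", "VR 1.0"]
        for rec in records:
            for tag, value in _record_fields(rec):
                if isinstance(value, list):
                    lines.append(f"{tag} {value[0]}")
                    lines.extend(f"   {v}" for v in value[1:])
                else:
                    lines.append(f"{tag} {value}")
            lines.append("ER")
            lines.append("")
        lines.append("EF")
        return "\n".join(lines) + "\n"
    if dialect == "tab":
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(_TAB_COLUMNS)
        for rec in records:
            fields = dict(_record_fields(rec))
            row = []
            for tag in _TAB_COLUMNS:
                value = fields.get(tag, "")
                if isinstance(value, list):
                    value = "; ".join(value)
                row.append(value)
            writer.writerow(row)
        return buf.getvalue()
    raise ValueError(f"unsupported dialect: {dialect!r}")


def write_corpus_table(records: list[BiblioRecord]) -> str:
    """Flat one-row-per-record CSV of the record model (list fields ';'-joined)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([
        "record_id", "title", "authors", "source", "pub_year", "doc_type",
        "language", "author_keywords", "keywords_plus", "affiliations",
        "countries", "times_cited", "doi",
    ])
    for rec in records:
        writer.writerow([
            rec.record_id, rec.title, ";".join(rec.authors), rec.source,
            rec.pub_year, rec.doc_type, rec.language,
            ";".join(rec.author_keywords), ";".join(rec.keywords_plus),
            ";".join(rec.affiliations), ";".join(rec.countries),
            rec.times_cited, rec.doi,
        ])
    return buf.getvalue()


def filter_records(records: list[BiblioRecord], corpus_filter: CorpusFilter | None = None) -> list[BiblioRecord]:
    """Apply inclusion criteria (document type, language, year range).

    Matching is case-insensitive on doc type and language. Counts kept and
    removed are logged; an empty result is allowed.
    """
    corpus_filter = corpus_filter or CorpusFilter()
    kept = [rec for rec in records if corpus_filter.matches(rec)]
    log.info("filter_records: kept %d, removed %d", len(kept), len(records) - len(kept))
    return kept


_PUNCT_RE = re.compile(r"[^\w\s]")


def _dedup_key(rec: BiblioRecord) -> tuple:
    if rec.doi:
        return ("doi", rec.doi.lower())
    title = _PUNCT_RE.sub("", rec.title.lower())
    title = " ".join(title.split())
    return ("title", title, rec.pub_year)


def deduplicate_records(records: list[BiblioRecord]) -> list[BiblioRecord]:
    """Collapse duplicates on lowercased DOI, else (normalized title, year).

    First occurrence wins; the number removed is logged.
    """
    seen: set[tuple] = set()
    out: list[BiblioRecord] = []
    for rec in records:
        key = _dedup_key(rec)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    log.info("deduplicate_records: removed %d duplicates", len(records) - len(out))
    return out


def default_alias_map() -> dict[str, str]:
    """Country alias table shipped with the package (editable CSV).

    Maps lowercased raw country tokens to standardized names; merges the UK
    constituents (England/Scotland/Wales/Northern Ireland) under
    "United Kingdom".
    """
    text = resources.files("psorimetrics").joinpath("data/country_aliases.csv").read_text()
    reader = csv.DictReader(io.StringIO(text))
    return {row["alias"].strip().lower(): row["canonical"].strip() for row in reader}


_DEFAULT_ALIASES: dict[str, str] | None = None

_ZIP_RE = re.compile(r"\b[A-Z]{1,2}[-\s]?\d[\w\s-]*$")  # trailing postal codes / state+ZIP


def _normalize_country_token(token: str) -> str:
    token = token.strip().strip(".").strip()
    # "MA 02115 USA", "W1T 4JF England" style endings: USA variants first
    if re.search(r"\bUSA\b", token) or re.search(r"\bUnited States\b", token, re.IGNORECASE):
        return "USA"
    # strip any leading state/postal prefix like "ON M5S 1A1" before the name
    token = re.sub(r"^[A-Z]{1,3}\s+[\w-]*\d[\w-]*\s+", "", token)
    token = re.sub(r"\s+\d[\w-]*$", "", token)
    return token.strip()


def extract_countries(affiliations: list[str], alias_map: dict[str, str] | None = None) -> list[str]:
    """Extract standardized country names from raw affiliation strings.

    The country is the last comma-separated token of each affiliation, trimmed
    of postal codes and USA variants, then passed through the alias map.
    Result is deduplicated in order of first appearance; affiliations with no
    recognizable country are skipped with a warning.
    """
    global _DEFAULT_ALIASES
    if alias_map is None:
        if _DEFAULT_ALIASES is None:
            _DEFAULT_ALIASES = default_alias_map()
        alias_map = _DEFAULT_ALIASES
    out: list[str] = []
    for aff in affiliations:
        if not aff.strip():
            continue
        token = aff.rsplit(",", 1)[-1]
        country = _normalize_country_token(token)
        if not country or not re.search(r"[A-Za-z]", country):
            log.warning("affiliation with no recognizable country skipped: %r", aff)
            continue
        country = alias_map.get(country.lower(), country)
        if country not in out:
            out.append(country)
    return out
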