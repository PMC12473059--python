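"""Thematic evolution across time periods and term-emergence timelines.

The corpus is sliced into consecutive periods (defaults: 1975-2000,
2001-2010, 2011-2025, matching the foundational / biological-revolution /
precision-targeting eras of systemic psoriasis therapy). Themes are keyword
communities of each period's co-occurrence network; inter-period flows weigh
the shared-keyword occurrence mass carried from one period's theme into the
next. Term timelines record when a keyword first appeared, its median
activity year, and how many documents used it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import BiblioRecord
from .networks import CoNetwork, NetworkConfig, build_cooccurrence, cluster_network


@dataclass
class EvolutionConfig:
    period_boundaries: list[tuple[int, int]] = field(
        default_factory=lambda: [(1975, 2000), (2001, 2010), (2011, 2025)])
    min_theme_docs: int = 100
    top_k_keywords: int = 50
    cluster_seed: int = 0
    keyword_source: str = "union"

    def __post_init__(self):
        spans = sorted(self.period_boundaries)
        for (lo, hi) in spans:
            if lo > hi:
                raise ValueError(f"invalid period [{lo}, {hi}]")
        for (_, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 <= hi:
                raise ValueError("overlapping period boundaries")


@dataclass
class Theme:
    period: int             # index into period_boundaries
    label: str              # representative (highest-occurrence) keyword
    members: set[str]
    doc_count: int


@dataclass
class ThemeFlow:
    source: Theme
    target: Theme
    weight: int


@dataclass
class TermTimeline:
    term: str
    first_year: int
    last_year: int
    median_year: int
    doc_count: int


def slice_periods(records: list[BiblioRecord], config: EvolutionConfig | None = None) -> list[list[BiblioRecord]]:
    """Partition records by publication year into the configured periods.

    Records outside every interval are excluded (with a warning via logging at
    the caller's discretion); overlapping intervals raise at config time.
    """
    config = config or EvolutionConfig()
    periods: list[list[BiblioRecord]] = [[] for _ in config.period_boundaries]
    for rec in records:
        for i, (lo, hi) in enumerate(config.period_boundaries):
            if lo <= rec.pub_year <= hi:
                periods[i].append(rec)
                break
    return periods


def _doc_count(records: list[BiblioRecord], members: set[str], keyword_source: str) -> int:
    return sum(1 for rec in records if members & set(rec.keywords(keyword_source)))


def extract_themes(period_records: list[BiblioRecord], period_index: int,
                   config: EvolutionConfig | None = None) -> list[Theme]:
    """Themes of one period: clusters of the top-k keyword co-occurrence network.

    Each cluster becomes a theme labeled by its highest-occurrence member;
    themes below ``min_theme_docs`` documents are dropped.
    """
    config = config or EvolutionConfig()
    if not period_records:
        return []
    net_cfg = NetworkConfig(min_keyword_occurrences=1, cluster_seed=config.cluster_seed)
    net = build_cooccurrence(period_records, config.keyword_source, net_cfg)
    if not net.nodes:
        return []
    top = sorted(net.nodes, key=lambda k: (-net.nodes[k]["occurrences"], k))[: config.top_k_keywords]
    top_set = set(top)
    sub = CoNetwork(
        nodes={k: dict(net.nodes[k]) for k in top},
        edges={p: w for p, w in net.edges.items() if p <= top_set},
    )
    labels = cluster_network(sub, net_cfg)
    clusters: dict[int, set[str]] = {}
    for kw, lab in labels.items():
        clusters.setdefault(lab, set()).add(kw)
    themes = []
    for lab in sorted(clusters):
        members = clusters[lab]
        label_kw = min(members, key=lambda k: (-sub.nodes[k]["occurrences"], k))
        count = _doc_count(period_records, members, config.keyword_source)
        if count >= config.min_theme_docs:
            themes.append(Theme(period=period_index, label=label_kw,
                                members=members, doc_count=count))
    themes.sort(key=lambda t: (-t.doc_count, t.label))
    return themes


def compute_flows(themes_t: list[Theme], themes_t1: list[Theme],
                  records_t1: list[BiblioRecord], keyword_source: str = "union") -> list[ThemeFlow]:
    """Flows between consecutive periods' themes.

    weight(A→B) = total occurrences, in period t+1 documents, of keywords in
    members(A) ∩ members(B); zero-weight flows are omitted.
    """
    occ: dict[str, int] = {}
    for rec in records_t1:
        for kw in set(rec.keywords(keyword_source)):
            occ[kw] = occ.get(kw, 0) + 1
    flows = []
    for a in themes_t:
        for b in themes_t1:
            shared = a.members & b.members
            weight = sum(occ.get(kw, 0) for kw in shared)
            if weight > 0:
                flows.append(ThemeFlow(source=a, target=b, weight=weight))
    flows.sort(key=lambda f: (-f.weight, f.source.label, f.target.label))
    return flows


def thematic_evolution(records: list[BiblioRecord], config: EvolutionConfig | None = None
                       ) -> tuple[list[list[Theme]], list[list[ThemeFlow]]]:
    """End-to-end: slice, extract per-period themes, compute consecutive flows."""
    config = config or EvolutionConfig()
    periods = slice_periods(records, config)
    themes = [extract_themes(recs, i, config) for i, recs in enumerate(periods)]
    flows = [
        compute_flows(themes[i], themes[i + 1], periods[i + 1], config.keyword_source)
        for i in range(len(periods) - 1)
    ]
    return themes, flows


def term_timeline(records: list[BiblioRecord], terms: list[str],
                  keyword_source: str = "union") -> list[TermTimeline]:
    """First/median/last activity years and document counts per term.

    The median year is the integer median of the containing documents'
    publication years; for an even count, the floor of the mean of the two
    middle values. Terms absent from the corpus are omitted. Invariant to
    record order.
    """
    out = []
    for term in terms:
        years = sorted(rec.pub_year for rec in records
                       if term in set(rec.keywords(keyword_source)))
        if not years:
            continue
        n = len(years)
        if n % 2 == 1:
            median = years[n // 2]
        else:
            median = (years[n // 2 - 1] + years[n // 2]) // 2
        out.append(TermTimeline(term=term, first_year=years[0], last_year=years[-1],
                                median_year=median, doc_count=n))
    return out


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_sankey_csv(flows_by_transition: list[list[ThemeFlow]]) -> str:
    """Sankey-ready CSV: source, target, weight, period pair."""
    lines = ["source,target,weight,period_pair"]
    for i, flows in enumerate(flows_by_transition):
        for f in flows:
            lines.append(f"{f.source.label},{f.target.label},{f.weight},{i}->{i + 1}")
    return "\n".join(lines) + "\n"


def write_timeline_csv(timelines: list[TermTimeline]) -> str:
    lines = ["term,first_year,median_year,last_year,doc_count"]
    for t in sorted(timelines, key=lambda t: (t.first_year, t.term)):
        lines.append(f"{t.term},{t.first_year},{t.median_year},{t.last_year},{t.doc_count}")
    return "\n".join(lines) + "\n"
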