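"""Keyword co-occurrence and country collaboration networks.

Networks follow the science-mapping conventions of VOSviewer: node
*occurrences* count documents containing an item (binary per document by
default), an edge's *link strength* counts documents containing both items,
and a node's *total link strength* (TLS) is the sum of its incident edge
weights. Community structure is found by seeded modularity optimization
(Louvain) with labels numbered by descending cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .records import BiblioRecord


@dataclass
class NetworkConfig:
    min_entity_docs: int = 10          # countries: "at least 10 documents"
    min_keyword_occurrences: int = 1
    counting: str = "full"             # full | fractional (node credit)
    binary_counting: bool = True       # per-document binary co-occurrence
    cluster_seed: int = 0
    cluster_resolution: float = 1.0

    def __post_init__(self):
        if self.min_entity_docs < 1 or self.min_keyword_occurrences < 1:
            raise ValueError("thresholds must be >= 1")
        if self.counting not in {"full", "fractional"}:
            raise ValueError(f"unknown counting mode: {self.counting!r}")


@dataclass
class CoNetwork:
    """Weighted undirected item network.

    ``nodes`` maps item → attribute dict (occurrences, weight, tls, cluster);
    ``edges`` maps frozenset pairs → link strength.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[frozenset, float] = field(default_factory=dict)

    def tls(self, item: str) -> float:
        if item not in self.nodes:
            raise KeyError(f"unknown item: {item!r}")
        return sum(w for pair, w in self.edges.items() if item in pair)

    def fill_tls(self) -> None:
        for item in self.nodes:
            self.nodes[item]["tls"] = self.tls(item)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for item, attrs in self.nodes.items():
            g.add_node(item, **attrs)
        for pair, w in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w)
        return g


def total_link_strength(network: CoNetwork, item: str) -> float:
    """Sum of incident edge weights for one item."""
    return network.tls(item)


def build_cooccurrence(records: list[BiblioRecord], keyword_source: str = "union",
                       config: NetworkConfig | None = None) -> CoNetwork:
    """Keyword co-occurrence network over (normalized) keyword fields.

    A keyword's occurrence count is the number of documents containing it;
    nodes below ``min_keyword_occurrences`` are removed before edges are
    built. With ``binary_counting`` (default) a document contributes at most
    one unit to any link.
    """
    config = config or NetworkConfig()
    occurrences: dict[str, int] = {}
    doc_sets: list[list[str]] = []
    for rec in records:
        kws = rec.keywords(keyword_source)
        uniq = sorted(set(kws)) if config.binary_counting else sorted(kws)
        doc_sets.append(uniq)
        for kw in set(kws):
            occurrences[kw] = occurrences.get(kw, 0) + 1
    keep = {k for k, n in occurrences.items() if n >= config.min_keyword_occurrences}
    net = CoNetwork()
    for k in sorted(keep):
        net.nodes[k] = {"occurrences": occurrences[k], "weight": occurrences[k]}
    for kws in doc_sets:
        present = [k for k in kws if k in keep]
        for a, b in combinations(sorted(set(present)) if config.binary_counting else present, 2):
            if a == b:
                continue
            pair = frozenset((a, b))
            net.edges[pair] = net.edges.get(pair, 0) + 1
    net.fill_tls()
    return net


def build_collaboration(records: list[BiblioRecord], config: NetworkConfig | None = None) -> CoNetwork:
    """Country collaboration network.

    Node credit follows ``config.counting``: full gives every listed country a
    whole document; fractional gives each of a record's k countries 1/k.
    Edges always count whole co-authored documents. Countries with fewer than
    ``min_entity_docs`` documents are dropped.
    """
    config = config or NetworkConfig()
    doc_counts: dict[str, int] = {}
    credit: dict[str, float] = {}
    country_lists: list[list[str]] = []
    for rec in records:
        countries = list(dict.fromkeys(rec.countries))
        if not countries:
            continue
        country_lists.append(countries)
        share = 1.0 if config.counting == "full" else 1.0 / len(countries)
        for c in countries:
            doc_counts[c] = doc_counts.get(c, 0) + 1
            credit[c] = credit.get(c, 0.0) + share
    keep = {c for c, n in doc_counts.items() if n >= config.min_entity_docs}
    net = CoNetwork()
    for c in sorted(keep):
        net.nodes[c] = {"occurrences": doc_counts[c], "weight": credit[c]}
    for countries in country_lists:
        present = sorted(set(countries) & keep)
        for a, b in combinations(present, 2):
            pair = frozenset((a, b))
            net.edges[pair] = net.edges.get(pair, 0) + 1
    net.fill_tls()
    return net


def cluster_network(network: CoNetwork, config: NetworkConfig | None = None) -> dict[str, int]:
    """Seeded modularity community detection over edge weights.

    Deterministic for a fixed seed; labels are contiguous integers starting at
    0, ordered by descending cluster size (ties broken by smallest member).
    Labels are also written onto the network's node attributes.
    """
    config = config or NetworkConfig()
    if not network.nodes:
        raise ValueError("cannot cluster an empty network")
    g = network.to_networkx()
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=config.cluster_resolution, seed=config.cluster_seed)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = {}
    for label, community in enumerate(ordered):
        for item in community:
            labels[item] = label
    for item, label in labels.items():
        network.nodes[item]["cluster"] = label
    return labels


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_vosviewer_map(network: CoNetwork) -> str:
    """VOSviewer map file: ``id label x y cluster weight`` (tab-separated).

    Layout coordinates are not computed; x and y are written as 0.
    """
    lines = ["id\tlabel\tx\ty\tcluster\tweight"]
    for i, item in enumerate(sorted(network.nodes), start=1):
        attrs = network.nodes[item]
        cluster = attrs.get("cluster", 0) + 1  # VOSviewer clusters are 1-based
        lines.append(f"{i}\t{item}\t0\t0\t{cluster}\t{attrs.get('weight', 0)}")
    return "\n".join(lines) + "\n"


def write_vosviewer_network(network: CoNetwork) -> str:
    """VOSviewer network file: ``source target strength`` by 1-based node id."""
    ids = {item: i for i, item in enumerate(sorted(network.nodes), start=1)}
    lines = []
    for pair in sorted(network.edges, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        lines.append(f"{ids[a]}\t{ids[b]}\t{network.edges[pair]}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_edge_list_csv(network: CoNetwork) -> str:
    lines = ["source,target,weight"]
    for pair in sorted(network.edges, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        lines.append(f"{a},{b},{network.edges[pair]}")
    return "\n".join(lines) + "\n"
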