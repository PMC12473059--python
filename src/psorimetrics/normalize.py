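"""Synonym resolution and terminology normalization for pharmaceutical keywords.

The normalizer resolves the orthographic and lexical variation that plagues
drug and target nomenclature in keyword fields ("TNF-α", "tnf alpha",
"TNFalpha"; "cyclosporin"/"cyclosporine") through a sequential three-stage
matcher:

1. **exact** — terms sharing a *collapse key* (core string with all hyphens,
   spaces and punctuation removed) are formatting variants of one another;
2. **semantic** — density clustering (DBSCAN) on cosine distance between term
   embeddings, with a pluggable embedding provider and a deterministic
   built-in character-trigram fallback;
3. **fuzzy** — token-set edit-distance similarity gated by domain rules on
   International Nonproprietary Name (INN) suffixes, so that distinct
   monoclonal antibodies ("infliximab" vs "ixekizumab") are never merged.

Candidate pairs are consolidated into synonym groups as connected components
of the pair graph; each group elects a canonical term (highest corpus
frequency, then shortest, then lexicographically smallest) and the result is
written as a VOSviewer-compatible thesaurus file.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from itertools import combinations

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN

from .records import BiblioRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TermEntry:
    raw: str
    core: str
    frequency: int = 1


@dataclass(frozen=True)
class SynonymPair:
    term_a: str
    term_b: str
    stage: str  # exact | semantic | fuzzy
    score: float

    def __post_init__(self):
        if self.term_a == self.term_b:
            raise ValueError("self-pair")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score out of [0,1]: {self.score}")


@dataclass
class SynonymGroup:
    canonical: str
    variants: set[str]
    support: int


@dataclass
class Thesaurus:
    """Variant → canonical mapping; idempotent under composition."""

    mapping: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def resolve(self, core: str) -> str:
        return self.mapping.get(core, core)


@dataclass
class NormalizationConfig:
    semantic_similarity_threshold: float = 0.90
    semantic_min_neighbors: int = 2
    fuzzy_score_threshold: float = 0.90
    min_group_size: int = 2
    embedding_provider: str = "builtin-trigram"

    def __post_init__(self):
        for name in ("semantic_similarity_threshold", "fuzzy_score_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")


@dataclass
class ValidationPlan:
    sample_size: int = 300
    n_raters: int = 3
    pass_threshold: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if not 0.0 < self.pass_threshold <= 1.0:
            raise ValueError("pass_threshold must be in (0,1]")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "κ": "kappa", "λ": "lambda", "μ": "mu", "σ": "sigma", "τ": "tau", "ω": "omega",
}
_DASHES = "‐‑‒–—―−"
_BRACKETED_RE = re.compile(r"[\(\[\{][^\)\]\}]*[\)\]\}]")


def preprocess_term(raw: str) -> str:
    """Standardize a raw keyword into its core form.

    Lowercases, maps Unicode dashes to "-", transliterates Greek letters,
    strips bracketed qualifiers, collapses whitespace, and trims leading and
    trailing punctuation. Raises ValueError if nothing remains.
    """
    if not raw or not raw.strip():
        raise ValueError("empty term")
    s = unicodedata.normalize("NFC", raw).lower()
    for dash in _DASHES:
        s = s.replace(dash, "-")
    for greek, latin in _GREEK.items():
        s = s.replace(greek, latin)
    s = _BRACKETED_RE.sub(" ", s)
    s = " ".join(s.split())
    s = s.strip(" -_.,;:!?'\"/\\")
    s = " ".join(s.split())
    if not s:
        raise ValueError(f"term empty after preprocessing: {raw!r}")
    return s


def collapse_key(core: str) -> str:
    """Core string with all hyphens, whitespace and punctuation removed."""
    return re.sub(r"[^0-9a-z]", "", core)


def build_term_entries(records: list[BiblioRecord], keyword_source: str = "union") -> list[TermEntry]:
    """Collect preprocessed terms with corpus frequencies (per occurrence)."""
    freq: dict[str, int] = {}
    raw_form: dict[str, str] = {}
    for rec in records:
        for kw in rec.keywords(keyword_source):
            try:
                core = preprocess_term(kw)
            except ValueError:
                continue
            freq[core] = freq.get(core, 0) + 1
            raw_form.setdefault(core, kw)
    return [TermEntry(raw=raw_form[c], core=c, frequency=n) for c, n in sorted(freq.items())]


# ---------------------------------------------------------------------------
# Stage 1: exact formatting variants
# ---------------------------------------------------------------------------

def stage_exact(terms: list[TermEntry]) -> list[SynonymPair]:
    """Link terms that are formatting variants (equal collapse keys)."""
    buckets: dict[str, list[str]] = {}
    for t in terms:
        buckets.setdefault(collapse_key(t.core), []).append(t.core)
    pairs = []
    for key in sorted(buckets):
        cores = sorted(set(buckets[key]))
        for a, b in combinations(cores, 2):
            pairs.append(SynonymPair(a, b, "exact", 1.0))
    return pairs


# ---------------------------------------------------------------------------
# Stage 2: semantic clustering
# ---------------------------------------------------------------------------

_EMBEDDING_PROVIDERS: dict[str, object] = {}


def register_embedding_provider(name: str, fn) -> None:
    """Register an external embedding provider: fn(list[str]) -> (n,d) array."""
    _EMBEDDING_PROVIDERS[name] = fn


def _trigram_embed(cores: list[str]) -> np.ndarray:
    """Binary character-trigram incidence vectors with padded term boundaries,
    L2-normalized. Deterministic and dependency-free."""
    grams_per_term = []
    vocab: set[str] = set()
    for core in cores:
        padded = f" {core} "
        grams = {padded[i:i + 3] for i in range(len(padded) - 2)}
        grams_per_term.append(grams)
        vocab |= grams
    index = {g: i for i, g in enumerate(sorted(vocab))}
    mat = np.zeros((len(cores), max(1, len(index))), dtype=float)
    for row, grams in enumerate(grams_per_term):
        for g in grams:
            mat[row, index[g]] = 1.0
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms


register_embedding_provider("builtin-trigram", _trigram_embed)


def embed_terms(terms: list[TermEntry], provider: str = "builtin-trigram") -> np.ndarray:
    """Embed term cores as unit-norm vectors.

    Unknown or failing providers fall back to the built-in trigram embedding
    with a logged warning, so the pipeline never hard-depends on external
    model weights.
    """
    cores = [t.core for t in terms]
    fn = _EMBEDDING_PROVIDERS.get(provider)
    if fn is None:
        log.warning("embedding provider %r unavailable; falling back to builtin-trigram", provider)
        fn = _trigram_embed
    try:
        vectors = np.asarray(fn(cores), dtype=float)
    except Exception:  # pragma: no cover - defensive fallback path
        log.warning("embedding provider %r failed; falling back to builtin-trigram", provider)
        vectors = _trigram_embed(cores)
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vectors / norms


def stage_semantic(vectors: np.ndarray, terms: list[TermEntry], config: NormalizationConfig) -> list[SynonymPair]:
    """Density clustering on cosine distance; within-cluster pairs become
    synonym candidates scored by their cosine similarity.

    eps = 1 - similarity threshold; a point is core when its eps-neighborhood
    (itself included) holds at least ``semantic_min_neighbors`` points. Noise
    points emit nothing.
    """
    if len(terms) < 2:
        return []
    eps = 1.0 - config.semantic_similarity_threshold
    labels = DBSCAN(eps=max(eps, 1e-12), min_samples=config.semantic_min_neighbors,
                    metric="cosine").fit_predict(vectors)
    pairs = []
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            clusters.setdefault(int(lab), []).append(i)
    for lab in sorted(clusters):
        members = clusters[lab]
        for i, j in combinations(members, 2):
            cos = float(np.clip(np.dot(vectors[i], vectors[j]), 0.0, 1.0))
            a, b = sorted((terms[i].core, terms[j].core))
            pairs.append(SynonymPair(a, b, "semantic", cos))
    return pairs


# ---------------------------------------------------------------------------
# Stage 3: fuzzy matching with INN domain rules
# ---------------------------------------------------------------------------

INN_SUFFIXES = ("-mab", "-cept", "-inib", "-tinib", "-ciclib")


def _drug_token(core: str) -> str | None:
    """Return the INN-suffixed token of a term, if any."""
    for token in core.replace("-", " - ").split():
        for suffix in INN_SUFFIXES:
            if token.endswith(suffix.lstrip("-")) and len(token) > len(suffix):
                return token
    return None


def _levenshtein_ratio(a: str, b: str) -> float:
    return SequenceMatcher(None, a, b).ratio()


def token_set_similarity(a: str, b: str) -> float:
    """Token-set edit-distance similarity in [0, 1].

    Invariant under token permutation: the shared-token prefix is compared
    against each side's remainder-augmented string and the best ratio wins —
    the classic token-set ratio construction.
    """
    tokens_a, tokens_b = set(a.split()), set(b.split())
    inter = " ".join(sorted(tokens_a & tokens_b))
    rest_a = " ".join(sorted(tokens_a - tokens_b))
    rest_b = " ".join(sorted(tokens_b - tokens_a))
    s1 = inter
    s2 = (inter + " " + rest_a).strip()
    s3 = (inter + " " + rest_b).strip()
    return max(
        _levenshtein_ratio(s1, s2),
        _levenshtein_ratio(s1, s3),
        _levenshtein_ratio(s2, s3),
    )


def fuzzy_pair_allowed(a: str, b: str) -> bool:
    """Domain validation for a candidate fuzzy pair.

    (a) two INN-suffixed drug terms must share their leading 4-character stem;
    (b) a drug-suffixed term never pairs with a non-drug term.
    """
    drug_a, drug_b = _drug_token(a), _drug_token(b)
    if drug_a and drug_b:
        return drug_a[:4] == drug_b[:4]
    if drug_a or drug_b:
        return False
    return True


def stage_fuzzy(terms: list[TermEntry], config: NormalizationConfig) -> list[SynonymPair]:
    """Score all candidate pairs by token-set similarity; emit those passing
    both the score threshold and the INN domain rules."""
    pairs = []
    cores = sorted({t.core for t in terms})
    for a, b in combinations(cores, 2):
        if not fuzzy_pair_allowed(a, b):
            continue
        score = token_set_similarity(a, b)
        if score >= config.fuzzy_score_threshold:
            pairs.append(SynonymPair(a, b, "fuzzy", min(score, 1.0)))
    return pairs


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def select_canonical(variants: set[str], frequencies: dict[str, int]) -> str:
    """Highest corpus frequency wins; ties break to the shortest string, then
    lexicographically smallest."""
    if not variants:
        raise ValueError("empty group")
    return min(variants, key=lambda v: (-frequencies.get(v, 0), len(v), v))


def merge_groups(pairs: list[SynonymPair], frequencies: dict[str, int],
                 config: NormalizationConfig | None = None) -> list[SynonymGroup]:
    """Consolidate pairs into synonym groups via connected components.

    Components smaller than ``min_group_size`` are discarded.
    """
    config = config or NormalizationConfig()
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.term_a, p.term_b)
    groups = []
    for component in nx.connected_components(graph):
        if len(component) < config.min_group_size:
            continue
        variants = set(component)
        groups.append(SynonymGroup(
            canonical=select_canonical(variants, frequencies),
            variants=variants,
            support=sum(frequencies.get(v, 0) for v in variants),
        ))
    groups.sort(key=lambda g: g.canonical)
    return groups


def build_thesaurus(groups: list[SynonymGroup]) -> Thesaurus:
    mapping = {}
    for g in groups:
        for v in sorted(g.variants):
            if v != g.canonical:
                mapping[v] = g.canonical
    return Thesaurus(mapping=mapping)


def apply_thesaurus(records: list[BiblioRecord], thesaurus: Thesaurus) -> list[BiblioRecord]:
    """Rewrite each record's keywords to canonical form.

    Unmapped keywords keep their preprocessed core form; duplicates within a
    record collapse (order of first appearance). Idempotent.
    """
    out = []
    for rec in records:
        new_rec = rec.copy()
        for attr in ("author_keywords", "keywords_plus"):
            seen: set[str] = set()
            rewritten: list[str] = []
            for kw in getattr(rec, attr):
                try:
                    core = preprocess_term(kw)
                except ValueError:
                    continue
                canon = thesaurus.resolve(core)
                if canon not in seen:
                    seen.add(canon)
                    rewritten.append(canon)
            setattr(new_rec, attr, rewritten)
        out.append(new_rec)
    return out


# ---------------------------------------------------------------------------
# Thesaurus I/O (VOSviewer-compatible)
# ---------------------------------------------------------------------------

def write_thesaurus(groups: list[SynonymGroup], dialect: str = "vosviewer-tab") -> str:
    """Serialize groups as a two-column thesaurus file.

    ``vosviewer-tab`` is VOSviewer's native tab-separated "label / replace by"
    format; ``csv`` is the comma-separated equivalent. Line order is sorted
    and deterministic.
    """
    if dialect == "vosviewer-tab":
        sep = "\t"
    elif dialect == "csv":
        sep = ","
    else:
        raise ValueError(f"unsupported thesaurus dialect: {dialect!r}")
    lines = [f"label{sep}replace by"]
    mapping = build_thesaurus(groups).mapping
    for variant in sorted(mapping):
        lines.append(f"{variant}{sep}{mapping[variant]}")
    return "\n".join(lines) + "\n"


def parse_thesaurus(text: str, dialect: str = "vosviewer-tab") -> Thesaurus:
    sep = "\t" if dialect == "vosviewer-tab" else ","
    lines = [ln for ln in text.splitlines() if ln.strip()]
    mapping = {}
    for ln in lines[1:]:  # skip header
        variant, canonical = ln.split(sep, 1)
        mapping[variant] = canonical
    return Thesaurus(mapping=mapping)


# ---------------------------------------------------------------------------
# Validation sampling and agreement scoring
# ---------------------------------------------------------------------------

def largest_remainder_allocation(sizes: list[int], total: int) -> list[int]:
    """Proportional integer allocation by the largest-remainder method."""
    pool = sum(sizes)
    if pool == 0:
        return [0] * len(sizes)
    exact = [s * total / pool for s in sizes]
    alloc = [int(e) for e in exact]
    remainder_order = sorted(range(len(sizes)), key=lambda i: (-(exact[i] - alloc[i]), i))
    for i in remainder_order[: total - sum(alloc)]:
        alloc[i] += 1
    return alloc


def sample_validation_pairs(pairs: list[SynonymPair], plan: ValidationPlan) -> list[SynonymPair]:
    """Stratified random sample of candidate pairs for expert review.

    Strata are the originating stages (exact/semantic/fuzzy); allocation is
    proportional with largest-remainder rounding; sampling is without
    replacement and reproducible under the plan's seed. If fewer pairs exist
    than requested, all are returned.
    """
    if not pairs:
        raise ValueError("no pairs available to sample")
    if len(pairs) <= plan.sample_size:
        return list(pairs)
    strata: dict[str, list[SynonymPair]] = {}
    for p in pairs:
        strata.setdefault(p.stage, []).append(p)
    stages = sorted(strata)
    alloc = largest_remainder_allocation([len(strata[s]) for s in stages], plan.sample_size)
    rng = np.random.default_rng(plan.seed)
    sample: list[SynonymPair] = []
    for stage, k in zip(stages, alloc):
        members = sorted(strata[stage], key=lambda p: (p.term_a, p.term_b))
        idx = rng.choice(len(members), size=min(k, len(members)), replace=False)
        sample.extend(members[i] for i in sorted(idx))
    return sample


def agreement_rate(annotations: list[list[bool]], plan: ValidationPlan) -> tuple[float, bool]:
    """Fraction of groups unanimously approved by all raters, plus pass flag.

    Each inner list must hold exactly ``plan.n_raters`` votes.
    """
    if not annotations:
        raise ValueError("no annotated groups")
    for votes in annotations:
        if len(votes) != plan.n_raters:
            raise ValueError(f"expected {plan.n_raters} votes per group, got {len(votes)}")
    unanimous = sum(1 for votes in annotations if all(votes))
    rate = unanimous / len(annotations)
    return rate, rate >= plan.pass_threshold


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    terms: list[TermEntry]
    pairs: list[SynonymPair]
    groups: list[SynonymGroup]
    thesaurus: Thesaurus
    records: list[BiblioRecord]


def normalize_corpus(records: list[BiblioRecord], config: NormalizationConfig | None = None,
                     keyword_source: str = "union") -> NormalizationResult:
    """Run the three matching stages, consolidate, and rewrite the corpus."""
    config = config or NormalizationConfig()
    terms = build_term_entries(records, keyword_source)
    frequencies = {t.core: t.frequency for t in terms}
    pairs = stage_exact(terms)
    vectors = embed_terms(terms, config.embedding_provider)
    pairs += stage_semantic(vectors, terms, config)
    pairs += stage_fuzzy(terms, config)
    # drop duplicate links found by multiple stages (first stage wins)
    seen: set[tuple[str, str]] = set()
    unique_pairs = []
    for p in pairs:
        key = tuple(sorted((p.term_a, p.term_b)))
        if key not in seen:
            seen.add(key)
            unique_pairs.append(p)
    groups = merge_groups(unique_pairs, frequencies, config)
    thesaurus = build_thesaurus(groups)
    rewritten = apply_thesaurus(records, thesaurus)
    return NormalizationResult(terms, unique_pairs, groups, thesaurus, rewritten)
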