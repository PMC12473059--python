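"""Synthetic WoS-style corpus generator with known ground truth.

The generator emulates the structural features of the five-decade psoriasis
pharmacotherapy corpus that the pipeline's stages consume, at desk scale:

* an exact per-year publication schedule over four growth phases
  (exploratory foundations, mechanistic era, biological-therapy revolution,
  precision-targeting era);
* era-weighted keyword themes (foundational mechanism terms, TNF-era
  biologics, clinical-trial methodology, modern IL-17/IL-23/JAK targets) that
  plant a recoverable co-occurrence community structure;
* orthographic variant injection (case shuffles, hyphen/space swaps, Greek
  transliteration swaps, whitespace padding) with a recorded variant →
  canonical ground truth;
* heavy-tailed, age-scaled citation counts (gamma-Poisson mixture, so the
  variance exceeds the mean and older papers accumulate more citations);
* four country blocks with within-block collaboration preference, planting a
  recoverable community structure in the collaboration network.

All randomness flows from a single seeded :class:`numpy.random.Generator`;
a fixed seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .normalize import Thesaurus, preprocess_term
from .records import BiblioRecord

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

DEFAULT_PHASES: list[tuple[int, int, int]] = [
    # (first_year, last_year, documents_per_year)
    (1975, 1990, 4),
    (1991, 2004, 12),
    (2005, 2015, 40),
    (2016, 2025, 130),
]

DEFAULT_THEMES: dict[str, list[str]] = {
    "foundations": [
        "psoriasis", "expression", "hla-dr expression", "in vitro",
        "human skin", "25-dihydroxyvitamin d3", "dithranol",
        "methotrexate", "cyclosporine", "etretinate",
    ],
    "tnf biologics": [
        "tnf-alpha", "infliximab", "etanercept", "adalimumab",
        "rheumatoid arthritis", "psoriatic arthritis", "monoclonal antibody",
    ],
    "clinical trials": [
        "double-blind trial", "safety", "efficacy", "controlled trial",
        "phase-iii", "quality of life",
    ],
    "modern targets": [
        "il-17", "il-23", "secukinumab", "ixekizumab", "ustekinumab",
        "guselkumab", "tofacitinib", "jak inhibitor",
    ],
}

# per-theme sampling weight in each growth phase (columns = phases)
DEFAULT_THEME_ERA_WEIGHTS: dict[str, list[float]] = {
    "foundations": [1.00, 0.60, 0.30, 0.15],
    "tnf biologics": [0.05, 0.50, 0.80, 0.50],
    "clinical trials": [0.10, 0.30, 0.60, 0.90],
    "modern targets": [0.00, 0.05, 0.30, 1.00],
}

DEFAULT_COUNTRY_BLOCKS: list[list[str]] = [
    ["USA", "Canada", "Brazil", "Mexico", "Argentina"],
    ["Germany", "United Kingdom", "France", "Switzerland"],
    ["Italy", "Spain", "Denmark", "Sweden", "Poland", "The Netherlands"],
    ["China", "Japan", "India", "South Korea", "Australia", "Egypt", "Saudi Arabia"],
]

DEFAULT_JOURNALS = [
    "Journal of the American Academy of Dermatology",
    "British Journal of Dermatology",
    "Journal of Investigative Dermatology",
    "Journal of the European Academy of Dermatology and Venereology",
    "Annals of the Rheumatic Diseases",
    "Journal of Rheumatology",
    "Lancet",
    "Dermatology",
]

VARIANT_RULES = ("case", "hyphen_space", "greek", "padding")


@dataclass
class SyntheticConfig:
    seed: int = 0
    year_range: tuple[int, int] = (1975, 2025)
    phase_schedule: list[tuple[int, int, int]] = field(
        default_factory=lambda: list(DEFAULT_PHASES))
    themes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_THEMES.items()})
    theme_era_weights: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_THEME_ERA_WEIGHTS.items()})
    variant_rules: tuple[str, ...] = VARIANT_RULES
    injection_probability: float = 0.15
    keywords_per_doc: tuple[int, int] = (4, 6)     # inclusive range
    hub_keyword: str = "psoriasis"
    hub_probability: float = 0.6                   # extra chance to include the hub term
    within_theme_probability: float = 0.8
    citation_scale: float = 1.5                    # expected citations per year of age
    citation_dispersion: float = 1.2               # gamma-Poisson shape (overdispersion)
    country_blocks: list[list[str]] = field(
        default_factory=lambda: [list(b) for b in DEFAULT_COUNTRY_BLOCKS])
    within_block_probability: float = 0.85
    n_countries_probs: tuple[float, ...] = (0.60, 0.30, 0.10)  # P(1), P(2), P(3) countries
    journals: list[str] = field(default_factory=lambda: list(DEFAULT_JOURNALS))

    def __post_init__(self):
        for p in (self.injection_probability, self.within_theme_probability,
                  self.within_block_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if not self.themes or not any(self.themes.values()):
            raise ValueError("vocabulary must be non-empty")
        lo, hi = self.year_range
        if lo > hi:
            raise ValueError("invalid year_range")
        blocks_flat = [c for b in self.country_blocks for c in b]
        if len(blocks_flat) != len(set(blocks_flat)):
            raise ValueError("country blocks must be disjoint")
        if abs(sum(self.n_countries_probs) - 1.0) > 1e-9:
            raise ValueError("n_countries_probs must sum to 1")

    def phase_of(self, year: int) -> int:
        for i, (lo, hi, _) in enumerate(self.phase_schedule):
            if lo <= year <= hi:
                return i
        raise ValueError(f"year {year} outside phase schedule")

    def schedule(self) -> dict[int, int]:
        out = {}
        for lo, hi, per_year in self.phase_schedule:
            for year in range(lo, hi + 1):
                out[year] = per_year
        return out


@dataclass
class GroundTruth:
    """What the generator actually injected, for scoring recovery."""

    variant_map: dict[str, str] = field(default_factory=dict)       # surface variant -> canonical
    observed_forms: dict[str, set[str]] = field(default_factory=dict)  # canonical -> surfaces used
    record_theme: dict[str, str] = field(default_factory=dict)      # record_id -> theme
    country_block: dict[str, int] = field(default_factory=dict)     # country -> block index
    schedule: dict[int, int] = field(default_factory=dict)          # year -> documents

    def to_json(self) -> str:
        return json.dumps({
            "variant_map": self.variant_map,
            "observed_forms": {k: sorted(v) for k, v in sorted(self.observed_forms.items())},
            "record_theme": self.record_theme,
            "country_block": self.country_block,
            "schedule": {str(k): v for k, v in sorted(self.schedule.items())},
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(
            variant_map=data["variant_map"],
            observed_forms={k: set(v) for k, v in data["observed_forms"].items()},
            record_theme=data["record_theme"],
            country_block={k: int(v) for k, v in data["country_block"].items()},
            schedule={int(k): v for k, v in data["schedule"].items()},
        )


# ---------------------------------------------------------------------------
# Variant injection
# ---------------------------------------------------------------------------

_GREEK_SWAPS = [("alpha", "α"), ("beta", "β"), ("gamma", "γ")]


def inject_variant(keyword: str, rules: tuple[str, ...], rng: np.random.Generator) -> str:
    """Perturb a keyword with one sampled formatting rule.

    All rules stay within the family that preprocessing plus collapse-key
    matching undoes, so every injected variant is recoverable by the exact
    matching stage. Rules that do not apply to a keyword (no hyphen or space
    to swap, no Greek name to swap) fall back to a case shuffle.
    """
    rule = rules[int(rng.integers(len(rules)))]
    if rule == "identity":
        return keyword
    if rule == "hyphen_space":
        if "-" in keyword:
            return keyword.replace("-", " ")
        if " " in keyword:
            return keyword.replace(" ", "-")
        rule = "case"
    if rule == "greek":
        for latin, greek in _GREEK_SWAPS:
            if latin in keyword:
                return keyword.replace(latin, greek)
        rule = "case"
    if rule == "padding":
        return f"  {keyword} "
    if rule == "case":
        flips = rng.random(len(keyword)) < 0.5
        return "".join(ch.upper() if flip else ch for ch, flip in zip(keyword, flips))
    raise ValueError(f"unknown variant rule: {rule!r}")


# ---------------------------------------------------------------------------
# Citations
# ---------------------------------------------------------------------------

def sample_citations(pub_year: int, config: SyntheticConfig, rng: np.random.Generator) -> int:
    """Heavy-tailed citation count with age-increasing expectation.

    Gamma-Poisson mixture: mean = citation_scale × document age (census year
    minus publication year), dispersion shape ``citation_dispersion``; the
    variance exceeds the mean whenever the mean is positive.
    """
    age = config.year_range[1] - pub_year
    mean = config.citation_scale * age
    if mean <= 0:
        return 0
    lam = rng.gamma(config.citation_dispersion, mean / config.citation_dispersion)
    return int(rng.poisson(lam))


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _sample_theme(phase: int, config: SyntheticConfig, rng: np.random.Generator) -> str:
    names = sorted(config.themes)
    weights = np.array([config.theme_era_weights[n][phase] for n in names], dtype=float)
    if weights.sum() == 0:
        weights[:] = 1.0
    return names[int(rng.choice(len(names), p=weights / weights.sum()))]


def _sample_countries(config: SyntheticConfig, rng: np.random.Generator) -> tuple[list[str], int]:
    n = 1 + int(rng.choice(len(config.n_countries_probs), p=config.n_countries_probs))
    home = int(rng.integers(len(config.country_blocks)))
    countries = [str(rng.choice(config.country_blocks[home]))]
    while len(countries) < n:
        if rng.random() < config.within_block_probability:
            block = home
        else:
            others = [i for i in range(len(config.country_blocks)) if i != home]
            block = others[int(rng.integers(len(others)))]
        c = str(rng.choice(config.country_blocks[block]))
        if c not in countries:
            countries.append(c)
    return countries, home


def generate_corpus(config: SyntheticConfig | None = None) -> tuple[list[BiblioRecord], GroundTruth]:
    """Generate a corpus following the configured schedule exactly.

    Deterministic for a fixed seed. Returns the record list together with the
    :class:`GroundTruth` of injected variants, per-record themes and country
    block labels.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(schedule=config.schedule())
    for block_idx, block in enumerate(config.country_blocks):
        for country in block:
            truth.country_block[country] = block_idx

    records: list[BiblioRecord] = []
    idx = 0
    for year in sorted(truth.schedule):
        phase = config.phase_of(year)
        for _ in range(truth.schedule[year]):
            record_id = f"SYN-{idx:05d}"
            theme = _sample_theme(phase, config, rng)
            vocab = config.themes[theme]
            all_vocab = sorted({kw for kws in config.themes.values() for kw in kws})

            k_lo, k_hi = config.keywords_per_doc
            n_kw = int(rng.integers(k_lo, k_hi + 1))
            chosen: list[str] = []
            if config.hub_keyword and rng.random() < config.hub_probability:
                chosen.append(config.hub_keyword)
            while len(chosen) < n_kw:
                pool = vocab if rng.random() < config.within_theme_probability else all_vocab
                kw = str(rng.choice(pool))
                if kw not in chosen:
                    chosen.append(kw)

            surfaces: list[str] = []
            for kw in chosen:
                if rng.random() < config.injection_probability:
                    variant = inject_variant(kw, config.variant_rules, rng)
                    if variant != kw:
                        truth.variant_map[variant] = kw
                    surfaces.append(variant)
                    truth.observed_forms.setdefault(kw, set()).add(variant)
                else:
                    surfaces.append(kw)
                    truth.observed_forms.setdefault(kw, set()).add(kw)

            half = (len(surfaces) + 1) // 2
            countries, _home = _sample_countries(config, rng)
            affiliations = [f"Univ {c.replace(' ', '')} {idx % 7}, {c}" for c in countries]
            rec = BiblioRecord(
                record_id=record_id,
                title=f"Synthetic study {idx} of {chosen[0]}",
                authors=[f"Author {int(rng.integers(200)):03d}", f"Author {int(rng.integers(200)):03d}"],
                source=str(rng.choice(config.journals)),
                pub_year=year,
                doc_type="Article" if rng.random() < 0.85 else "Review",
                language="English",
                author_keywords=surfaces[:half],
                keywords_plus=surfaces[half:],
                affiliations=affiliations,
                countries=countries,
                times_cited=sample_citations(year, config, rng),
                doi=f"10.5555/synth.{idx:05d}",
            )
            truth.record_theme[record_id] = theme
            records.append(rec)
            idx += 1
    return records, truth


# ---------------------------------------------------------------------------
# Ground-truth scoring
# ---------------------------------------------------------------------------

def score_variant_recovery(truth: GroundTruth, thesaurus: Thesaurus) -> float:
    """Fraction (in %) of injected canonicals whose observed surface forms all
    resolve to a single final term through the thesaurus.

    Only canonicals with at least one injected non-identity variant count
    toward the denominator; a canonical is recovered when preprocessing plus
    thesaurus lookup collapses every surface form it appeared under to one
    string.
    """
    scored = 0
    recovered = 0
    variant_canonicals = set(truth.variant_map.values())
    for canonical, forms in truth.observed_forms.items():
        if canonical not in variant_canonicals:
            continue
        scored += 1
        resolved = {thesaurus.resolve(preprocess_term(form)) for form in forms}
        if len(resolved) == 1:
            recovered += 1
    if scored == 0:
        return 100.0
    return 100.0 * recovered / scored
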