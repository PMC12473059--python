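# Methods

This note documents the models, conventions and design choices behind
`psorimetrics`, in the spirit of the methods documentation that mature
analysis libraries ship alongside their APIs.

## Corpus model and ingestion

A corpus is a list of `BiblioRecord`s. The parser supports the two common
export forms of the Web of Science Core Collection: the field-tagged plain
format (two-letter tags, three-space continuation lines, `PT`…`ER` blocks)
and the tab-delimited variant. Unknown tags are preserved verbatim in
`raw_fields`, which makes `parse ∘ write` the identity on the record model —
a property the tests exercise on both dialects. Missing `TC` parses as 0
(absence of a citation count in an export means "none recorded"); a record
with an unparseable `PY` is skipped with a warning rather than aborting a
multi-thousand-record ingest, while a structurally broken block (no `ER`)
aborts with the record index, since truncation usually means a corrupted
file.

Inclusion criteria default to articles and reviews in English, 1975–2025 —
the standard design for keyword-based mapping studies, where letters and
non-English records add noise to text fields without contributing citation
structure. Deduplication keys on the lowercased DOI when present, else on
(normalized title, year); title normalization is lowercase, punctuation
stripped, whitespace collapsed. Countries come from the last comma token of
each affiliation, trimmed of postal codes and US state/ZIP tails, then
passed through an editable alias table that merges UK constituents under
"United Kingdom" and standardizes common database spellings
("Peoples R China", "Fed Rep Ger").

## Terminology normalization

Pharmaceutical keyword fields mix formatting variants, spelling variants
and genuinely distinct drugs with near-identical names. The resolver runs
three matchers in sequence and then consolidates:

1. **Preprocessing** lowercases, maps Unicode dashes to "-", transliterates
   Greek letters (α→alpha …), strips bracketed qualifiers, collapses
   whitespace and trims flanking punctuation.
2. **Exact stage.** Terms sharing a *collapse key* (core with everything
   but alphanumerics removed) are linked with score 1. This single rule
   subsumes the hyphen/space/case/padding variant family.
3. **Semantic stage.** Terms are embedded as unit vectors and clustered
   with DBSCAN on cosine distance, `eps = 1 − 0.90`, neighborhood size 2
   (a point plus one neighbor suffices for a core point — the natural
   minimum for pairwise synonymy). All within-cluster pairs are emitted,
   scored by cosine. The embedding provider is pluggable; the built-in
   default is a binary character-trigram incidence embedding over
   space-padded terms, chosen because it is deterministic, dependency-free
   and adequate at vocabulary scale. Transformer embeddings can be
   registered behind the same contract; when a requested provider is
   unavailable the built-in takes over with a logged warning. Note that
   boundary padding is conservative: it lowers the cosine of
   suffix-variant pairs (e.g. cyclosporin/cyclosporine sits at 0.87 under
   the trigram fallback), which the fuzzy stage then catches.
4. **Fuzzy stage.** Token-set similarity — the classic construction that
   compares the shared-token prefix against each side's
   remainder-augmented string, making the score permutation-invariant —
   with a 0.90 threshold on the [0,1] scale, built on
   `difflib.SequenceMatcher`. Two domain rules gate every candidate:
   terms whose tokens carry an INN drug suffix (`-mab`, `-cept`, `-inib`,
   `-tinib`, `-ciclib`) only pair when their leading 4-character stems
   agree, and a drug-suffixed term never pairs with a non-drug term. This
   is what keeps infliximab and ixekizumab apart at any string similarity.

Pairs become an undirected graph; connected components of size ≥ 2 become
synonym groups (smaller components carry no merging information). The
canonical term is the variant with the highest corpus frequency, ties
broken by shortest string then lexicographic order — frequency is the best
proxy for the community's preferred surface form. The thesaurus is written
in VOSviewer's tab-separated "label / replace by" format (a comma dialect
is also provided), with sorted, deterministic line order.

Applying the thesaurus is idempotent by construction: canonicals never
appear as variants of other canonicals, and re-normalizing an already
normalized corpus yields singleton components that are discarded. The test
suite verifies this end to end.

For human validation, a stratified sampler draws (by default) 300 pairs
without replacement, stratified by originating stage with
largest-remainder proportional allocation, seeded for reproducibility.
`agreement_rate` scores the fraction of groups unanimously approved by
three raters against a 0.90 pass bar. Stratification by stage was chosen
because the three matchers have distinct error profiles; sampling
proportionally preserves the collection's composition.

## Citation indicators

All age-dependent denominators count years inclusively
(`ref_year − year + 1`): a journal first publishing in 1980 has, at a 2025
census, 46 publishing years. Printed ratios use round-half-up — 2 decimals
for TC/year, normalized TC and per-document averages, 3 for the
m-quotient. These two conventions jointly reproduce every derived ratio in
the published country/journal/top-cited tables exactly, which the
acceptance suite asserts.

h- and g-index use the standard ranked-vector scans and are tested against
brute-force oracles on random citation vectors; `g ≥ h` always. Per-entity
aggregation supports both full counting (every listed country credited a
whole document and the record's full TC) and fractional counting (1/k per
country); both are exposed because mapping tools differ on this point, and
full credit always dominates fractional credit per country.

## Networks

Co-occurrence counting is binary per document (VOSviewer's default):
occurrences count containing documents, link strength counts documents
containing both endpoints, total link strength sums incident weights.
A multiset mode exists behind a flag. Country collaboration edges count
whole co-authored documents in both credit modes — fractionalization
applies to node credit only, the simplest consistent reading of the two
counting philosophies. Countries under the 10-document threshold are
dropped before edge construction.

Clustering is Louvain modularity maximization over edge weights, with an
explicit seed and resolution; labels are renumbered contiguously by
descending cluster size (ties by smallest member) so runs are comparable.
Louvain was preferred over greedy agglomeration because the pipeline
promises seeded determinism end to end and Louvain exposes the seed
directly. Exact cluster membership is not a contract — community detection
on modularity has no unique optimum — but disconnected cliques, uniform
complete graphs and planted four-block corpora are all recovered, the last
with adjusted Rand index 1.0 at default settings.

## Thematic evolution

Periods default to 1975–2000, 2001–2010 and 2011–2025 — the foundational,
biological-revolution and precision-targeting eras. Themes are the
communities of each period's top-k keyword co-occurrence network, labeled
by their highest-occurrence member and kept when covering ≥ 100 documents.
Flow weight from theme A (period t) to theme B (period t+1) is the total
occurrence count, in period t+1 documents, of the keywords in
`members(A) ∩ members(B)` — shared vocabulary mass carried forward. An
inclusion-index weighting is a plausible alternative; the shared-member
definition was chosen for its direct document-level interpretation.
Term timelines report first and last occurrence years, the integer median
year (even counts: floor of the mean of the two middle values, matching the
convention of printing integer median years) and containing-document
counts.

## Synthetic corpus

The generator is the package's test bed and defines its study conditions:

* **Schedule.** Four phases — 1975–1990 at 4 docs/year, 1991–2004 at 12,
  2005–2015 at 40, 2016–2025 at 130 — echoing the field's documented
  growth phases at roughly one-tenth scale (1,972 records), a size chosen
  so the full pipeline runs in seconds. Counts are exact, not expected
  values.
* **Vocabulary.** Four keyword themes (foundational mechanisms, TNF-era
  biologics, clinical-trial methodology, modern targeted agents) with
  per-phase sampling weights that shift dominance across eras; a hub term
  ("psoriasis") is added to 60% of records to mimic the real network's hub
  structure. Documents draw 4–6 keywords, 80% from their theme.
* **Variants.** Each keyword occurrence is independently perturbed with
  probability 0.15 by one of four formatting rules (case shuffle,
  hyphen↔space swap, Greek↔transliteration swap, whitespace padding) —
  exactly the family the exact stage's collapse key undoes, with the
  variant→canonical pair recorded as ground truth.
* **Citations.** Gamma-Poisson with mean 1.5 × age and shape 1.2: the
  expectation grows linearly with document age (matching the citation-lag
  shape of mean-citation curves) and the variance exceeds the mean.
* **Countries.** Four regional blocks; 1–3 countries per document
  (probabilities 0.6/0.3/0.1), additional countries drawn from the home
  block with probability 0.85.

All draws flow from one seeded `numpy` generator; a fixed seed reproduces
the corpus byte for byte.

**Recovery metric.** A canonical term counts as recovered when *all* of its
observed surface forms resolve to a single final string through the
thesaurus. This is the operationally meaningful definition — downstream
counting only needs variants unified, whichever surface form wins — and it
is structurally guaranteed for the formatting family even when the
unperturbed base form happens never to be sampled, unlike the naive
"maps to the vocabulary spelling" definition.

What the generator does *not* emulate: realistic author/institution
structure, citation links between records (no `CR` parsing anywhere),
abstracts, multilingual records, or the absolute magnitudes of a licensed
corpus (≈19k documents, four-digit TLS values). Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure, not statistical fidelity to any real literature.

## Pipeline and reproducibility

`run_pipeline` executes the stages in a fixed order, writes every artifact
with deterministic (sorted) serialization, and records SHA-256 checksums,
counts, the seed and package versions in `manifest.json`. A failure aborts
with the stage name; the manifest flags the partial run. Determinism under
a fixed seed is a tested contract: two runs of `run-all` at default size
produce identical checksums in well under a minute on one CPU.

## Known limitations

* The exact-stage collapse key treats all punctuation as noise; terms
  distinguished only by punctuation (rare in keyword fields) would merge.
* The trigram fallback embedding is a lexical, not semantic, model: true
  synonyms with unrelated spellings (e.g. brand vs generic names) are out
  of its reach and require an external embedding provider.
* Institution extraction uses the first affiliation token, which conflates
  departments of differently formatted addresses.
* Fractional counting is applied to node credit only; edge fractionalization
  (as some tools implement) is not offered.
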