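"""Thematic evolution across the three study periods and term timelines."""

import psorimetrics as pm

records, truth = pm.generate_corpus(pm.SyntheticConfig(seed=0))
normalized = pm.normalize_corpus(records)

# periods: 1975-2000 (foundations), 2001-2010 (biologics), 2011-2025 (targeted)
cfg = pm.EvolutionConfig(min_theme_docs=30, cluster_seed=0)
themes, flows = pm.thematic_evolution(normalized.records, cfg)

for i, period_themes in enumerate(themes):
    lo, hi = cfg.period_boundaries[i]
    print(f"period {lo}-{hi}: "
          + ", ".join(f"{t.label} ({t.doc_count} docs)" for t in period_themes))

print("\nstrongest flows between consecutive periods "
      "(shared-keyword occurrence mass in the later period):")
for i, transition in enumerate(flows):
    for f in transition[:3]:
        print(f"  {f.source.label} -> {f.target.label}: {f.weight}")

# when did each therapeutic term first appear, and for how long was it active?
timelines = pm.term_timeline(normalized.records,
                             ["methotrexate", "infliximab", "secukinumab"])
print("\nterm emergence (first / median / last year, documents):")
for t in timelines:
    print(f"  {t.term:14s} {t.first_year} / {t.median_year} / {t.last_year}  "
          f"({t.doc_count} docs)")
# Conventional systemics appear decades before the targeted biologics,
# mirroring the field's therapeutic waves.
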