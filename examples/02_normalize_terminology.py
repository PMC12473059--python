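"""Resolve pharmaceutical terminology variants into a VOSviewer thesaurus.

A tiny corpus carries formatting variants ("TNF alpha" vs "tnf-alpha"),
near-identical spellings ("cyclosporin"/"cyclosporine") and two distinct
monoclonal antibodies that must NOT be merged (infliximab vs ixekizumab).
"""

import psorimetrics as pm

docs = [
    ["TNF-alpha", "psoriasis"],
    ["TNF alpha", "infliximab"],
    ["tnfalpha", "Infliximab"],
    ["cyclosporin", "psoriasis"],
    ["cyclosporine", "psoriasis"],
    ["ixekizumab", "psoriasis"],
    ["infliximab", "psoriasis"],
]
records = [pm.BiblioRecord(record_id=str(i), pub_year=2020, author_keywords=kws)
           for i, kws in enumerate(docs)]

result = pm.normalize_corpus(records)
print("synonym groups (canonical <- variants):")
for g in result.groups:
    variants = sorted(v for v in g.variants if v != g.canonical)
    print(f"  {g.canonical:12s} <- {variants}  (support={g.support})")

print("\nVOSviewer thesaurus file:")
print(pm.write_thesaurus(result.groups, dialect="vosviewer-tab"))
# 'infliximab' and 'ixekizumab' stay separate: both carry the -mab suffix but
# their 4-character INN stems differ, so the domain rule blocks the merge.
print("keywords after normalization of doc 1:",
      pm.apply_thesaurus(records, result.thesaurus)[1].author_keywords)
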