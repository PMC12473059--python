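"""Parse a field-tagged bibliographic export, apply the corpus inclusion
criteria (articles/reviews, English, 1975-2025), and deduplicate."""

import psorimetrics as pm

EXPORT = """\
FN Demo export
VR 1.0
PT J
TI Secukinumab in plaque psoriasis
SO British Journal of Dermatology
LA English
DT Article
DE Psoriasis; Secukinumab
C1 Univ Toronto, Toronto, Canada
TC 12
PY 2014
DI 10.1111/demo.1
ER

PT J
TI Methotrexate in psoriasis: a letter
SO Lancet
LA English
DT Letter
DE Methotrexate
C1 Cardiff Univ, Wales
TC 2
PY 1998
DI 10.1111/demo.2
ER

PT J
TI Secukinumab in plaque psoriasis
SO British Journal of Dermatology
LA English
DT Article
DE Psoriasis; Secukinumab
C1 Univ Toronto, Toronto, Canada
TC 12
PY 2014
DI 10.1111/DEMO.1
ER

EF
"""

records = pm.parse_wos_export(EXPORT, dialect="plain")
print(f"parsed records:       {len(records)}")

kept = pm.filter_records(records)  # default: {Article, Review} x {English}, 1975-2025
print(f"after inclusion rules: {len(kept)}  (the Letter is excluded)")

unique = pm.deduplicate_records(kept)
print(f"after deduplication:   {len(unique)}  (same DOI differing only in case)")

rec = unique[0]
print(f"countries extracted:   {rec.countries}  (last affiliation token, standardized)")
# A UK constituent such as 'Wales' would be standardized to 'United Kingdom'.
print(f"'Cardiff Univ, Wales' -> {pm.extract_countries(['Cardiff Univ, Wales'])}")
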