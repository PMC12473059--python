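"""Citation indicators: h/g-index, m-quotient, TC/year, normalized TC.

Inputs here are printed journal/top-paper statistics (h-index with first
publication year; total citations with publication year), evaluated at a
2025 census year.
"""

import psorimetrics as pm

citations = [10, 8, 5, 4, 3]
print(f"citation vector {citations}")
print(f"  h-index = {pm.h_index(citations)}   (4 papers with >= 4 citations)")
print(f"  g-index = {pm.g_index(citations)}   (top 5 papers hold 30 >= 5^2 citations)")

# m-quotient: h-index per inclusive year of publishing history
print(f"\nm-quotient, h=105 publishing since 1980, census 2025: "
      f"{pm.m_index(105, 1980, 2025)}")
print(f"m-quotient, h=41 publishing since 2013, census 2025:  "
      f"{pm.m_index(41, 2013, 2025)}  (young venue, fast impact)")

# per-year citation rate of a landmark 2014 trial with 1613 citations
print(f"\nTC/year, 1613 citations since 2014: {pm.tc_per_year(1613, 2014, 2025)}")

# normalized TC: citations relative to same-year average
print(f"normalized TC, 6 citations in a year averaging 4: {pm.normalized_tc(6, 4.0)}")

# per-document citation average of a country with 300,339 citations on 5,959 docs
print(f"avg citations/doc, 300339/5959: {pm.avg_citations_per_doc(300_339, 5959)}")
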