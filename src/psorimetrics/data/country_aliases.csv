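alias,canonical
england,United Kingdom
scotland,United Kingdom
wales,United Kingdom
north ireland,United Kingdom
northern ireland,United Kingdom
uk,United Kingdom
u.k.,United Kingdom
united kingdom,United Kingdom
usa,USA
u.s.a.,USA
united states,USA
united states of america,USA
peoples r china,China
p.r. china,China
pr china,China
china,China
netherlands,The Netherlands
the netherlands,The Netherlands
holland,The Netherlands
fed rep ger,Germany
germany,Germany
west germany,Germany
south korea,South Korea
korea,South Korea
republic of korea,South Korea
czech republic,Czechia
czechia,Czechia
russia,Russia
russian federation,Russia
turkiye,Turkey
turkey,Turkey
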