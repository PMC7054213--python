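# Example per-sample signature allow-lists for `sigtool attribute --rules`.
#
# Keys are sample ids; values list the signatures permitted for that
# sample. Samples not listed may use every signature. This is where
# biological-plausibility rules live (e.g. allowing a tobacco-associated
# signature only in lung or head-and-neck samples); the toolkit ships no
# built-in rule table.
LUNG-001: [S1, S2, S4]
LUNG-002: [S1, S2, S4]
LIVER-001: [S1, S2]
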