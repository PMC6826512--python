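gene	total_interactions
Act5C	68
Chc	37
Cul3	83
Cyt-c-d	97
Dark	106
Dredd	73
Dronc	71
Duba	195
Fadd	151
Lasp	47
Mer	45
Past1	90
aux	29
blanks	97
didum	190
eIF3m	134
jar	100
klhl10	140
shi	150
skap	110
sw	188
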