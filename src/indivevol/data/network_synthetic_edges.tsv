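node_a	node_b	type
Act5C	Chc	physical
Act5C	Cyt-c-d	physical
Act5C	Dark	physical
Act5C	Dronc	physical
Chc	Cul3	physical
Chc	Cyt-c-d	physical
Chc	klhl10	physical
Cyt-c-d	Cul3	physical
Cyt-c-d	Dark	physical
Cyt-c-d	aux	physical
Cyt-c-d	blanks	physical
Dark	Cul3	physical
Dredd	Duba	physical
Dronc	Dredd	physical
Dronc	Duba	physical
Dronc	Fadd	physical
Lasp	Mer	physical
Lasp	Past1	physical
Lasp	skap	physical
Mer	Past1	physical
aux	blanks	physical
aux	sw	physical
blanks	jar	physical
didum	eIF3m	physical
jar	eIF3m	physical
klhl10	shi	physical
skap	shi	physical
sw	shi	physical
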