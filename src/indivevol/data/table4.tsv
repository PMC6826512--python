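gene	sex_biased	duplicated	in_network	rate_x1e3	rate_sd_x1e3	ucld_stdev	age_mean	age_low	age_high	coleoptera_paraphyletic
hmw	1	0	0	9.67	1.349	2.972	-	-	-	0
Dark	0	0	1	5.27	0.282	0.418	264.2	214.3	314.2	0
blanks	1	1	1	4.38	0.382	0.483	310.6	248.2	376.1	0
Dredd	0	0	1	4.23	0.219	0.309	278.4	239.2	315.8	0
Fadd	0	0	1	4.21	0.277	0.345	-	-	-	0
Dronc	0	1	1	3.62	0.221	0.391	379.8	339.5	426.0	1
Duba	0	0	1	3.18	0.257	0.566	348.2	248.5	450.2	1
nsr	1	1	0	3.00	0.279	0.672	194.1	127.4	262.5	0
Bug22	0	1	0	2.82	0.278	0.559	-	-	-	0
scat	1	0	0	2.73	0.259	>3	267.8	185.8	359.0	0
aux	0	0	1	2.45	0.154	0.386	311.0	252.3	372.7	0
nes	0	0	0	2.27	0.130	0.423	307.2	253.7	365.2	1
poe	0	0	0	2.10	0.174	>3	328.7	227.3	433.1	0
Osbp	0	1	0	2.05	0.180	0.601	299.6	230.3	375.4	1
Npc1a	0	1	0	1.91	0.157	>3	334.2	231.5	442.6	0
didum	0	0	1	1.90	0.126	0.511	337.0	264.9	419.9	0
Pen	0	1	0	1.78	0.120	0.531	273.2	208.2	340.5	0
klhl10	1	1	1	1.69	0.124	0.816	-	-	-	0
Prosalpha6T	1	1	0	1.68	0.151	0.559	248.5	185.6	315.1	0
oys	0	0	0	1.57	0.127	0.558	-	-	-	0
gudu	1	0	0	1.45	0.115	0.553	347.7	258.1	444.1	0
Ance	0	1	0	1.42	0.099	0.396	-	-	-	0
sw	0	0	1	1.38	0.171	3.712	247.5	133.2	374.3	0
Taz	0	0	0	1.33	0.111	0.607	312.2	231.9	401.0	0
Mer	0	0	1	1.30	0.130	0.936	304.5	208.4	409.9	0
skap	0	1	1	1.15	0.116	0.557	314.4	214.9	424.3	1
CdsA	0	0	0	1.15	0.103	0.629	350.5	258.6	440.6	1
jar	0	0	1	1.06	0.086	0.482	403.2	315.0	494.6	1
porin	0	0	0	0.99	0.106	0.779	-	-	-	0
Lasp	0	0	1	0.98	0.138	0.930	451.5	288.4	633.0	1
Cul3	0	1	1	0.98	0.130	3.798	223.1	112.6	351.7	1
EcR	0	0	0	0.93	0.091	0.789	-	-	-	0
heph	0	0	0	0.90	0.118	3.919	-	-	-	0
eIF3m	0	0	1	0.86	0.084	0.480	363.0	277.4	462.1	0
shi	0	0	1	0.74	0.092	3.847	253.2	124.3	397.0	0
Past1	0	1	1	0.71	0.069	0.713	387.4	273.0	513.2	1
Vps28	0	0	0	0.63	0.079	0.822	-	-	-	0
gish	0	1	0	0.47	0.070	4.174	262.9	137.6	401.9	0
mlt	0	0	0	0.42	0.523	3.268	244.6	121.4	368.1	1
Chc	0	0	1	0.32	0.035	0.700	346.6	242.1	464.4	0
orb2	0	1	0	0.24	0.035	1.414	180.4	52.1	328.6	0
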