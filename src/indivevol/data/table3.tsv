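gene	n_seqs	n_species	n_single_copy_species	median_len	rel_rate	aligned_n	aligned_len	model_name
Act5C	517	115	7	376	0.60	-	-	-
Ance	238	109	30	631	0.92	90	621	LG + G + I
aux	136	112	94	1164	1.21	126	1755	JTT + G + I + F
blanks	172	107	71	348	1.55	122	719	JTT + G + I + F
Bug22	201	115	36	200	0.61	83	270	LG + G + I
CdsA	118	109	101	445	0.76	122	574	JTT + G + I + F
Chc	123	115	110	1676	0.63	130	1726	JTT + G + I
ctp	121	98	79	89	0.57	-	-	-
Cul3	153	116	91	780	0.73	133	858	JTT + G + I
Cyt-c-d	148	110	74	108	0.65	-	-	-
Dark	119	106	94	1378	1.99	112	2193	JTT + G + I + F
didum	126	113	102	1793	1.10	124	2175	LG + G + I
Dredd	91	81	75	493	1.76	98	676	JTT + G + I + F
Dronc	128	96	78	425	1.67	119	654	WAG + G + I + F
Duba	105	99	93	628	0.95	113	1087	JTT + G + I + F
EcR	121	113	105	515	0.83	120	576	JTT + G + I
eIF3m	116	113	111	387	0.77	130	394	JTT + G + I
Fadd	96	93	90	246	1.77	108	353	JTT + G + I + F
gish	129	113	99	441	0.73	124	401	JTT + G + I
gudu	125	115	106	689	1.01	124	658	LG + G + I
heph	206	114	47	285	0.78	114	597	JTT + G + I + F
hmw	78	76	74	260	1.38	80	925	JTT + G + I + F
jar	131	111	97	1238	0.86	129	1375	JTT + G + I + F
klhl10	214	109	54	619	0.96	113	630	LG + G + I
Lasp	113	105	97	321	0.79	121	298	JTT + G + I
Mer	120	112	105	605	0.87	129	686	JTT + G + I
mlt	124	112	103	477	1.10	130	651	LG + G + I + F
nes	122	112	104	474	1.21	128	472	LG + G + I + F
Npc1a	216	116	23	1256	0.98	124	1435	LG + G + I
nsr	317	115	38	355	0.92	129	563	JTT + G + I
orb2	115	106	98	351	0.62	105	293	JTT + G + I
Osbp	158	112	79	597	0.91	130	1094	JTT + G + I
oys	121	108	97	505	1.03	115	463	LG + G + I
Past1	124	114	104	534	0.66	120	564	LG + G + I
Pen	342	116	7	519	0.83	121	593	LG + G + I + F
poe	183	115	84	2949	1.08	129	3846	JTT + G + I + F
porin	124	108	98	282	0.86	127	286	LG + G + I + F
Prosalpha6T	126	108	91	277	0.77	125	312	LG + G + I + F
scat	130	116	103	942	1.11	133	1233	JTT + G + I
shi	133	113	94	857	0.67	132	1005	LG + G + I
skap	247	116	8	424	0.80	128	476	LG + G + I
sw	125	115	109	655	0.80	133	755	JTT + G + I
Taz	105	102	99	265	0.91	118	303	LG + G + I + F
Vps28	135	112	94	212	0.72	131	213	LG + G + I
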