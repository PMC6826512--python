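gene	n_species	aligned_len	model_name	rate_x1e3	rate_sd_x1e3	ucld_stdev
Cul3	25	2196	TN93 + G + I	11.90	2.603	2.707
gish	24	1197	GTR + G + I	9.34	1.981	2.821
Act5C	15	1128	GTR + G + I	8.91	2.232	2.839
scat	25	1974	GTR + G + I	7.26	1.397	2.958
eIF3m	25	1155	GTR + G + I	7.06	1.394	2.872
poe	23	3291	GTR + G + I	6.90	1.322	2.844
Dredd	23	732	GTR + G + I	6.41	1.255	3.012
CdsA	21	1323	GTR + G + I	6.35	1.229	2.954
blanks	25	672	GTR + G + I	5.82	1.172	2.994
shi	25	2610	GTR + G + I	5.81	1.161	2.918
skap	24	1302	GTR + G + I	5.09	0.984	3.033
Dark	14	1863	GTR + G + I	4.96	0.905	2.947
Duba	20	858	GTR + G + I	4.93	0.997	2.916
Prosalpha6T	25	822	GTR + G + I	4.90	0.959	3.041
Chc	22	4944	GTR + G + I	4.78	0.410	0.270
klhl10	14	1779	GTR + G + I	4.48	0.849	2.952
jar	25	3393	GTR + G + I	4.47	0.840	3.005
didum	21	5073	GTR + G + I	4.41	0.817	3.029
oys	14	1347	GTR + G + I	4.41	0.839	3.019
ctp	8	267	GTR + G	3.79	1.107	0.232
mlt	24	1248	GTR + G + I	3.61	0.464	0.474
sw	25	1455	GTR + G + I	3.61	0.347	0.344
Taz	23	774	GTR + G + I	3.52	0.278	0.340
Fadd	19	228	GTR + G + I	3.41	0.495	0.463
nsr	24	780	GTR + G + I	3.39	0.464	0.409
orb2	8	834	GTR + G + I	3.36	0.834	0.477
Npc1a	23	3756	GTR + G + I	3.32	0.280	0.255
Dronc	24	954	GTR + G + I	3.17	0.265	0.221
EcR	17	1278	GTR + G + I	3.13	0.396	0.382
Vps28	26	573	GTR + G + I	3.12	0.509	0.169
Osbp	25	1881	GTR + G + I	3.09	0.285	0.365
Past1	13	1566	GTR + G + I	3.09	0.344	0.186
aux	18	2130	GTR + G + I	3.09	0.295	0.252
Lasp	25	423	GTR + G + I	3.08	0.495	0.110
gudu	15	1848	GTR + G + I	2.93	0.280	0.450
Pen	24	1440	GTR + G + I	2.92	0.252	0.296
porin	25	849	GTR + G + I	2.78	0.393	0.499
Mer	23	1701	GTR + G + I	2.78	0.260	0.329
Ance	18	1716	GTR + G + I	2.59	0.198	0.299
hmw	8	201	GTR + G	2.57	0.457	0.118
nes	25	1317	GTR + G + I	2.08	0.171	0.538
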