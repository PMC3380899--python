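protein	sites	peptide	accession	charge	expected_mh	light_wt	light_s6	light_mock	heavy_wt	heavy_s6	heavy_mock	ratio_wt	ratio_s6	ratio_mock	unnorm_pct_wt	unnorm_pct_s6	unmod_pct_wt	unmod_pct_s6	norm_pct_wt	norm_pct_s6
hnRNP A0	R291-Me2	R.SNSGPYR[Me2]GGYGGGGGYGGSSF.-	NP_006796.1	2	1968.8470	780	665	340	926	990	729	0.842	0.671	0.466	181	144	176	172	103	83.9
Arg/Ser-rich 10 (Tra-2)	R241-Me2	R.SYR[Me2]GGGGGGGGWR.A	NP_004584.1	3	1251.5976	961	1040	772	1610	2250	1960	0.596	0.462	0.393	152	117	103	66.4	147	177
FUS/TLS	R216-Me2,R218-Me2	R.GGR[Me2]GR[Me2]GGSGGGGGGGGGGYNR.S	NP_004951.1	3	1762.8439	852	768	370	846	1110	534	1.01	0.689	0.692	145	100	95.9	104	152	95.5
hnRNP U	R733-Me2,R739-Me2	R.R[Me2]GNMPQR[Me2]GGGGGGSGGIGYPYPR.A	NP_114032.2	3	2304.1413	390	345	98.1	727	975	320	0.536	0.354	0.307	175	115	114	92	154	126
hnRNP U	R733-Me2,R739-Me2	R.R[Me2]GNM[Ox]PQR[Me2]GGGGGGSGGIGYPYPR.A	NP_114032.2	4	2320.1362	654	457	408	1150	1140	1440	0.567	0.400	0.284	200	141	114	92	176	154
THO complex subunit 4	R204-Me2	R.NR[Me2]GAGGFGGGGGTR.R	NP_005773.3	3	1248.6191	1750	622	838	1710	646	1430	1.03	0.962	0.588	174	164	135	112	130	147
hnRNP A/B	R322-Me2	R.R[Me2]GGHQNNYKPY.-	NP_004490.2	3	1361.6708	1720	756	781	1780	1520	1320	0.965	0.497	0.591	163	84.1	112	104	146	81.2
hnRNP D0	R345-Me2	R.R[Me2]GGHQNSYKPY.-	NP_112738.1	3	1334.6599	2380	2090	1610	2120	2220	1670	1.12	0.941	0.964	116	97.7	104	87.4	112	112
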