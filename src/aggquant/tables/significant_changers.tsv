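accession	gene	direction	n_mock	n_tdp43	n_tdps6	d43	ds6	ds6_43	group
NP_031401.1	TARDBP	up	9	26	26	3.51	6.32	2.81	both
NP_001005849.1	SUMO2	up	2	4	4	1.64	1.95	0.31	both
NP_006319.1	RBM14	up	11	14	14	1.18	1.55	0.37	both
NP_006784.1	PRDX3	up	7	7	2	0.98	1.34	0.36	both
NP_006749.1	U2AF1	up	2	2	2	0.96	1.26	0.30	both
NP_006796.1	HNRNPA0	up	10	10	9	1.21	1.03	-0.18	both
NP_004387.1	DDX5	up	28	34	23	1.14	0.89	-0.25	both
NP_004915.2	ACTN4	down	66	36	36	-2.32	-1.76	0.56	both
NP_005955.1	MYH10	down	136	71	109	-1.87	-1.28	0.59	both
NP_001605.1	ACTG1	down	56	54	49	-1.83	-1.04	0.79	both
NP_001035203.1	MYH11	down	25	11	23	-1.63	-0.90	0.73	both
NP_005745.1	G3BP1	up	7	7	12	0.28	1.70	1.43	s6
NP_002945.1	RPS27A	up	6	6	5	-0.02	1.35	1.37	s6
NP_002559.2	PABPC1	up	19	19	16	0.76	1.25	0.49	s6
NP_001407.1	EIF4A1	up	26	33	25	0.81	1.03	0.22	s6
NP_031389.3	NONO	up	19	23	21	0.72	1.02	0.30	s6
NP_006550.1	KHDRBS1	up	8	4	5	0.41	0.99	0.58	s6
NP_006089.1	GNB2L1	up	11	8	10	0.72	0.96	0.24	s6
NP_001027454.1	TMPO	up	5	6	8	0.46	0.93	0.47	s6
NP_004153.2	RAB5A	down	2	3	4	-0.77	-1.32	-0.55	s6
NP_000960.2	RPL5	up	2	6	4	1.20	0.64	-0.56	43
NP_004517.2	MCM2	up	6	4	11	1.08	0.03	-1.05	43
NP_001009570.1	CCT7	up	3	4	4	1.06	0.42	-0.64	43
NP_005057.1	SFPQ	up	18	20	13	0.99	0.75	-0.24	43
NP_005234.1	EWSR1	up	4	2	2	0.99	0.33	-0.66	43
NP_000997.1	RPS3A	up	7	10	4	0.98	0.59	-0.39	43
NP_002873.1	RANBP1	up	5	5	6	0.97	0.76	-0.21	43
NP_003964.3	RPL14	up	5	6	5	0.96	0.58	-0.38	43
NP_444505.1	RPLP0	up	8	11	8	0.95	0.54	-0.42	43
NP_006266.2	SRSF6	up	3	4	7	0.95	0.41	-0.54	43
NP_036611.2	YWHAG	up	12	18	12	0.95	0.52	-0.43	43
NP_001367.2	DYNC1H1	up	38	25	39	0.94	0.28	-0.66	43
NP_000958.1	RPL3	up	9	20	13	0.92	0.57	-0.35	43
NP_001460.1	XRCC6	up	29	39	23	0.91	0.38	-0.53	43
NP_859047.1	PRDX1	up	14	13	17	0.91	0.88	-0.04	43
NP_006126.1	CAPZA1	down	6	4	5	-1.20	-0.80	0.41	43
NP_057018.1	NOP58	down	22	29	20	0.33	-0.73	-1.06	lost_s6
NP_001354.1	DKC1	down	8	15	8	0.32	-0.36	-0.68	lost_s6
NP_002583.1	PCNA	down	5	7	5	0.80	0.10	-0.70	lost_s6
NP_006017.1	H1FX	down	4	3	3	0.55	-0.17	-0.72	lost_s6
NP_001348.2	DHX9	down	52	45	55	0.74	0.08	-0.66	lost_s6
NP_001203.1	C1QBP	down	8	10	8	0.84	0.17	-0.67	lost_s6
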