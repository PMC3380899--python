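site	peptide	charge	xcorr	delta_cn	matched_ions	mh_printed	segment
K84	R.K[GG]M[Ox]DETDASSAVK.V	2	2.31	0.35	14/22	1411.6369	1
K84	R.K[GG]MDETDASSAVK.V	2	2.79	0.49	13/22	1395.6420	1
K95	K.M[Ox]DETDASSAVK[GG]VK.R	2	3.95	0.14	19/24	1510.7053	1
K95	R.KMDETDASSAVK[GG]VK.R	2	4.01	0.10	18/26	1622.8054	1
K181	K.LPNSK[GG]QSQDEPLR.S	2	3.46	0.49	16/24	1625.8241	1
K160	R.FTEYETQVK[GG]VM[Ox]SQR.H	2	3.53	0.54	17/26	1875.8905	2
K160	R.FTEYETQVK[GG]VMSQR.H	2	4.03	0.61	20/26	1859.8956	2
K145	K.TGHSK[GG]GFGFVR.F	2	2.38	0.55	15/20	1306.6651	2
K136	K.EYFSTFGEVLM[Ox]VQVK[GG]K.D	2	3.84	0.07	18/30	2035.0204	2
K102	R.AVQK[GG]TSDLIVLGLPWK.T	2	5.34	0.56	23/30	1882.0796	3
K114	K.TSDLIVLGLPWK[GG]TTEQDLK.E	2	3.97	0.25	23/36	2271.2230	3
K224	R.EFFSQYGDVM[Ox]DVFIPK[GG]PFR.A	2	2.39	0.55	16/36	2452.1641	3
K121	K.TTEQDLK[GG]EYFSTFGEVLM[Ox]VQVK.K	3	4.13	0.54	27/84	2722.3280	4
K121	K.TTEQDLK[GG]EYFSTFGEVLMVQVK.K	3	3.17	0.42	21/84	2706.3330	4
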