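subfamily	id	ccc	cxcc	cxcxc	xccx	cxc	xxcxx	total_cys	pct_cys	length
CdMT	TpigMT-1	4	2	0	6	2	0	34	28.81	118
CdMT	TpyrMT-1	4	2	0	5	1	1	31	28.97	107
CdMT	TpyrMT-2	6	5	0	6	4	1	54	29.83	181
CdMT	TtheMTT1	6	3	0	8	2	1	48	29.63	162
CdMT	TtheMTT3	2	2	1	9	3	3	42	25.93	162
CdMT	TtheMTT5	1	1	0	5	1	6	24	24.24	99
CdMT	TrosMTT1	4	2	0	6	2	0	34	30.09	113
CdMT	TtroMTT1	6	3	0	8	2	0	47	30.13	156
CdMT	TmobMT1	6	3	0	9	3	0	51	29.65	172
CdMT	TvorMT1	6	3	0	8	2	1	48	28.40	169
CdMT	ThegMT1	4	2	0	6	2	0	34	27.87	122
CdMT	ThegMT2	4	1	0	8	7	4	49	25.65	191
CdMT	ThegMT3	6	3	0	9	3	0	51	28.65	178
CdMT	ThegMT4	5	1	0	8	6	4	50	25.91	193
CdMT	TborMTT1	4	2	0	6	2	0	34	30.09	113
CdMT	TborMTT2	5	2	2	9	1	2	49	30.06	163
CdMT	TelliMTT1	6	3	0	7	1	2	45	29.22	154
CdMT	TelliMTT2	6	3	0	6	0	3	42	28.97	145
CdMT	TmalaMTT1	6	3	0	8	2	1	48	29.63	162
CdMT	TmalaMTT2	5	3	0	8	1	2	44	27.16	162
CdMT	TmalaMTT3	2	2	0	12	2	6	46	25.70	179
CdMT	TmalaMTT4	1	1	0	7	1	3	25	25.25	99
CdMT	TpatMTT1	4	2	0	6	2	0	34	29.06	117
CdMT	TpatMTT2	4	2	0	6	3	3	39	26.35	148
CdMT	TamerMTT1	4	2	0	5	1	1	31	29.25	106
CdMT	TamerMTT2	6	3	0	8	2	1	48	30.57	157
CuMT	TpigMT-2	0	0	0	1	12	2	28	29.17	96
CuMT	TtheMTT2	0	0	0	0	15	2	32	29.63	108
CuMT	TtheMTT4	0	0	0	0	15	2	32	29.63	108
CuMT	TrosMTT2	0	0	0	1	9	2	22	28.21	78
CuMT	TtroMT1	0	0	0	1	12	2	28	28.00	100
CuMT	TtroMT2	0	0	0	0	15	2	32	26.63	108
CuMT	sp1.7-MT1	0	1	0	0	14	1	32	26.63	108
CuMT	TelliMTT6	0	0	0	0	21	2	44	29.73	148
CuMT	TelliMTT8	0	0	0	0	12	2	26	28.89	90
CuMT	TmalaMTT5	0	0	0	0	15	2	32	29.63	108
CuMT	TborMTT3	0	0	0	1	21	0	44	27.85	158
CuMT	TborMTT4	0	0	0	1	6	2	16	26.67	60
CuMT	TborMTT6	0	0	0	1	21	0	44	27.85	158
CuMT	TborMTT7	0	0	0	0	21	0	42	28.19	149
CuMT	TborMTT8	0	0	0	1	9	2	22	28.21	78
CuMT	TamerMTT3	0	0	0	0	14	3	31	28.97	107
CuMT	ImMTT2	0	0	0	0	27	0	54	32.34	167
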