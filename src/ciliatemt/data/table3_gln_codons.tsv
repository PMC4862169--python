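subfamily	id	caa	uaa	uag	cag	total
CdMT	TpigMT-1	3	1	0	0	4
CdMT	TpyrMT-1	0	0	0	0	0
CdMT	TpyrMT-2	2	10	2	0	14
CdMT	TtheMTT1	2	4	1	0	7
CdMT	TtheMTT3	2	5	1	1	9
CdMT	TtheMTT5	2	1	0	0	3
CdMT	TrosMTT1	2	2	0	0	4
CdMT	TtroMTT1	3	1	0	0	4
CdMT	TmobMT1	4	1	0	0	5
CdMT	TvorMT1	4	0	0	0	4
CdMT	ThegMT1	2	2	0	0	4
CdMT	ThegMT2	2	4	2	0	8
CdMT	ThegMT3	1	3	0	1	5
CdMT	ThegMT4	1	10	5	1	17
CdMT	TborMTT1	2	4	0	0	6
CdMT	TborMTT2	3	3	1	0	7
CdMT	TelliMTT1	1	6	2	0	9
CdMT	TelliMTT2	3	5	3	0	11
CdMT	TmalaMTT1	1	5	1	0	7
CdMT	TmalaMTT2	3	3	1	0	7
CdMT	TmalaMTT3	2	5	0	0	7
CdMT	TmalaMTT4	0	5	0	0	5
CdMT	TpatMTT1	2	4	1	0	7
CdMT	TpatMTT2	2	4	5	0	11
CdMT	TamerMTT1	1	4	1	0	6
CdMT	TamerMTT2	2	4	1	0	7
CuMT	TpigMT-2	6	0	0	0	6
CuMT	TtheMTT2	4	0	0	0	4
CuMT	TtheMTT4	4	0	0	0	4
CuMT	TrosMTT2	5	0	0	0	5
CuMT	TtroMT1	5	0	0	1	6
CuMT	TtroMT2	2	0	1	1	4
CuMT	sp1.7-MT1	3	2	2	0	7
CuMT	TelliMTT6	5	1	0	0	6
CuMT	TelliMTT8	3	2	0	0	5
CuMT	TmalaMTT5	3	1	0	0	4
CuMT	TborMTT3	4	7	2	0	13
CuMT	TborMTT4	2	0	0	0	2
CuMT	TborMTT6	4	7	2	0	13
CuMT	TborMTT7	5	2	1	0	8
CuMT	TborMTT8	5	0	0	0	5
CuMT	TamerMTT3	4	0	0	0	4
CuMT	ImMTT2	1	9	0	0	10
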