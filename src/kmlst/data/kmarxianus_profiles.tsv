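strain	IPP1	TFC1	GPH1	GSY2	SGA1	source	dst
LM127	1	1	1	1	1	Parmigiano Reggiano	1
LM30	1	1	1	1	1	Parmigiano Reggiano	1
LM38	1	1	1	1	1	Parmigiano Reggiano	1
LM3	1	1	1	1	14	Parmigiano Reggiano	2
LM50	1	1	1	1	14	Parmigiano Reggiano	2
LM96	1	1	1	1	14	Parmigiano Reggiano	2
LM47	1	1	1	1	18	Parmigiano Reggiano	3
LM32	1	1	1	2	1	Parmigiano Reggiano	4
LM6	1	1	1	4	2	Parmigiano Reggiano	5
LM42	1	1	1	17	16	Parmigiano Reggiano	6
LM36	1	1	6	1	1	Parmigiano Reggiano	7
CBS 1555	1	1	8	1	1	culture collection	8
CBS 712	1	1	8	1	1	culture collection	8
CBS 7858	1	1	8	1	1	culture collection	8
CBS 608	1	1	8	1	1	culture collection	8
6M2	1	1	10	3	4	Parmigiano Reggiano	9
CBS 834T	1	1	11	1	4	culture collection	10
VG6	1	1	16	17	2	cow's milk whey	11
K326	1	1	26	16	4	Parmigiano Reggiano	12
M169	1	1	26	17	4	Pecorino di Farindola	13
M38	1	1	26	17	4	Pecorino di Farindola	13
LM139	1	4	1	1	1	Parmigiano Reggiano	14
LM133	1	4	1	1	15	Parmigiano Reggiano	15
CBS 7894	1	3	9	22	1	culture collection	16
1SC4	1	6	13	12	15	Parmigiano Reggiano	17
LM116	1	7	1	7	15	Parmigiano Reggiano	18
LM72	1	12	4	1	1	Parmigiano Reggiano	19
LM28	1	19	5	28	1	Parmigiano Reggiano	20
LM169	1	20	27	13	24	Parmigiano Reggiano	21
LM142	1	21	7	1	25	Parmigiano Reggiano	22
CBS 2762	1	25	28	8	14	culture collection	23
CBS 1596	1	32	21	1	1	culture collection	24
LM141	1	33	1	1	1	Parmigiano Reggiano	25
LM92	1	33	8	20	1	Parmigiano Reggiano	26
LM174	1	34	2	19	22	Parmigiano Reggiano	27
LM9	1	35	1	1	14	Parmigiano Reggiano	28
LM14	2	1	1	1	3	Parmigiano Reggiano	29
LM48	3	1	1	5	1	Parmigiano Reggiano	30
LM136	4	9	4	6	15	Parmigiano Reggiano	31
LM17	5	15	1	10	23	Parmigiano Reggiano	32
LM114	6	23	1	18	1	Parmigiano Reggiano	33
LM153	7	17	3	11	21	Parmigiano Reggiano	34
VG1	8	11	22	22	11	cow's milk whey	35
VG4	8	11	22	22	11	cow's milk whey	35
M41	8	13	22	17	4	Pecorino di Farindola	36
M83	8	14	22	17	4	Pecorino di Farindola	37
M12	9	1	26	17	4	Pecorino di Farindola	38
M123	9	1	26	17	4	Pecorino di Farindola	38
M131	9	1	26	17	4	Pecorino di Farindola	38
M135	9	1	26	17	4	Pecorino di Farindola	38
M166	9	1	26	17	4	Pecorino di Farindola	38
M48	9	1	26	17	4	Pecorino di Farindola	38
M68	9	1	26	17	4	Pecorino di Farindola	38
M14	9	1	26	17	5	Pecorino di Farindola	39
M81	10	13	22	17	4	Pecorino di Farindola	40
LM44	11	1	1	1	15	Parmigiano Reggiano	41
CBS 397	12	1	8	1	1	culture collection	42
LM161	13	26	14	14	20	Parmigiano Reggiano	43
LM15	13	27	12	15	17	Parmigiano Reggiano	44
LM154	13	37	16	32	20	Parmigiano Reggiano	45
FM09	14	31	29	29	15	fermented milk	46
NCYC 179	15	1	19	1	7	culture collection	47
CBS 6432	15	1	24	1	7	culture collection	48
UCKM1	15	36	17	33	6	unpasteurized milk	49
CCT 7735	16	22	26	30	15	culture collection	50
NCYC 1424	16	28	14	9	14	culture collection	51
CBS 5795	16	29	14	9	14	culture collection	52
LM54	17	12	4	1	1	Parmigiano Reggiano	53
CBS 5668	19	24	15	25	14	culture collection	54
BO339	18	3	30	34	8	culture collection	55
KCTC 17555T	20	5	25	21	13	culture collection	56
CBS 6556	20	5	25	21	13	culture collection	56
NBRC 1777	21	1	22	22	11	culture collection	57
CBS 4857	21	10	18	23	9	culture collection	58
DMKU 3-1042	22	11	22	22	10	culture collection	59
LM148	23	11	18	31	26	Parmigiano Reggiano	60
IIPE453	22	11	22	22	11	culture collection	61
CBS 745	24	30	20	26	11	culture collection	62
DMB1	25	11	18	22	12	culture collection	63
LM20	26	18	13	24	19	Parmigiano Reggiano	64
LM167	27	16	18	27	11	Parmigiano Reggiano	65
CBS 2233	28	8	23	23	11	culture collection	66
CBS 4354	28	8	23	23	11	culture collection	66
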