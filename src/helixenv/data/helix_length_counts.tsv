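length	DM1	DM1_e	DM1_ne	DM2	DM2_e	DM2_ne
5	81	0	81	1463	1	1462
6	177	1	176	1768	14	1754
7	97	2	95	1549	10	1539
8	133	1	132	1173	3	1170
9	62	0	62	1212	2	1210
10	100	0	100	1619	6	1613
11	107	1	106	1692	12	1680
12	87	0	87	1657	3	1654
13	111	0	111	1222	1	1221
14	92	2	90	1215	5	1210
15	131	1	130	882	6	876
16	44	0	44	643	1	642
17	27	0	27	572	28	544
18	50	0	50	490	1	489
19	52	0	52	392	0	392
20	20	2	18	323	3	320
21	21	0	21	428	1	427
22	23	0	23	194	0	194
23	12	0	12	99	0	99
24	18	0	18	123	0	123
25	41	0	41	126	0	126
26	4	0	4	61	0	61
27	14	0	14	106	0	106
28	19	0	19	56	0	56
29	10	0	10	84	0	84
30	3	1	2	41	1	40
31	9	0	9	46	0	46
32	18	0	18	60	0	60
33	12	0	12	37	0	37
34	0	0	0	17	0	17
35	4	0	4	6	0	6
36	2	0	2	4	0	4
37	1	0	1	5	0	5
38	1	0	1	3	0	3
39	1	0	1	1	0	1
40	2	1	1	4	1	3
41	0	0	0	1	0	1
42	1	0	1	1	0	1
43	1	0	1	7	0	7
44	1	0	1	1	0	1
45	2	0	2	3	0	3
48	1	0	1	1	0	1
50	2	0	2	2	0	2
51	7	0	7	7	0	7
54	0	0	0	1	0	1
55	1	0	1	1	0	1
60	0	0	0	1	0	1
62	2	0	2	2	0	2
66	0	0	0	1	0	1
67	1	0	1	1	0	1
71	0	0	0	1	0	1
107	0	0	0	1	0	1
108	1	0	1	1	0	1
109	0	0	0	1	0	1
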