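mode	unscaled	scaled	experimental	notation	assignment
1	14	14		tau_ring	ring torsion CCCC (22) (ring C-B) + torsion OCCC (21) (ring C-B) + torsion HCC=C (11) (ring C-B) + torsion HCCC (11) (ring C-B)
2	36	35		tau_ring	ring torsion (12) (ring C-B)
3	54	52		tau_ring	ring torsion (19) (ring C-B)
4	59	57		tau_ring	ring torsion CCOC (12) (ring A-methyl) + torsion COCH (10) (methoxy)
5	81	78		tau_ring	ring torsion (26) (ring C)
6	105	102		gamma_methyl	(CH3 twist + ring torsion) (11) (ring A) + ring torsion (10) (A-C)
7	162	157		tau_ring	ring torsion (21) (ring C)
8	180	174		omega_CH	CH2 wagging (ring A)
9	189	183		gamma_CH	CH2 twist (methyl) (27) (ring A)
10	212	205		gamma_CH	CH2 twist (methyl) (12) (ring A)
11	222	215		gamma_OH	OH o.o.p. bending (20) (ring B) + ring torsion (16) (ring B)
12	233	225		tau_ring	ring torsion (87) (ring B)
13	236	228		gamma_CH	CH2 twist (methyl) (27) (ring A)
14	248	240		tau_ring	ring torsion (23) (ring B)
15	255	247		tau_ring	ring torsion (21) (ring A-C) + methyl torsion (15) (ring A)
16	290	280		tau_ring	CCOH torsion (15) (ring A)
17	297	287		tau_ring	CCOH torsion (10) (ring A)
18	310	300		gamma_OH	OH o.o.p. bending (69) (ring B)
19	329	318		gamma_OH	OH o.o.p. bending (52) (ring B)
20	338	327		delta_COH	COH bending (16) (ring B)
21	348	337		tau_ring	CCOH torsion (ring A)
22	392	379		gamma_OH	OH o.o.p. bending (46) (ring A)
23	417	403	419	tau_methyl	(methyl + CCOH) torsion (11) (ring A)
24	455	440		delta_ring	ring bending (12) (ring C)
25	478	462	459	tau_CH	CH2 twist (16) (ring C)
26	522	505	499	tau_ring	ring torsion (ring B)
27	526	509	507	tau_ring	ring torsion (ring A + B)
28	536	518		gamma_CH	CH2 twist (ring C) + ring torsion (ring C)
29	546	528	528	gamma_CH	CH2 twist (ring C)
30	561	542	553	gamma_CH	CH2 twist (ring C)
31	594	574	563	omega_CH3	CH3 wagging (ring A) + ring torsion (ring B)
32	615	595	597	gamma_CH	CH o.o.p. bending (ring B) (30) + ring torsion (17) (ring B)
33	620	600	582	gamma_CH	CCH o.o.p. bending (14) (ring A) + ring torsion (11) (ring A)
34	631	610	606	gamma_CH	CCH o.o.p. bending (ring B)
35	638	617	621	gamma_CH	CCH o.o.p. bending (ring A)
36	652	630	631	tau_ring	ring torsion (17) (ring A)
37	671	649	656	tau_ring	ring torsion (ring C)
38	687	664	664	gamma_CH	CH o.o.p. bending (26) (ring B)
39	713	689	688	gamma_CH	CCH o.o.p. bending (12) (ring B)
40	746	721	715	gamma_CH	CCH o.o.p. bending (16) (ring A)
41	781	755	759	gamma_CH	CCH o.o.p. bending (13) (ring A)
42	792	766		gamma_CH	CCH o.o.p. bending (21) (ring A)
43	819	792		gamma_CH	CH o.o.p. bending (41) (ring B)
44	834	806		gamma_CH	CH o.o.p. bending (42) (ring B)
45	844	816	815	gamma_CH	CH o.o.p. bending (28) (ring A)
46	875	846	858	gamma_CH	CH o.o.p. bending (38) (ring A)
47	896	866	874	gamma_CH	CH2 twist (20) (ring C)
48	974	942	939	tau_ring	ring torsion (ring C) + ring bending (ring A) + OC stretching (methyl)
49	996	963	964	tau_ring	ring torsion (ring C) + OC stretching (methyl)
50	1007	974		delta_ring	ring bending (ring B)
51	1011	978	977	delta_ring	ring bending (ring B)
52	1027	993	998	delta_CCH	CCH bending (ring B) + ring bending (ring B)
53	1054	1019	1028	nu_ring	ring breathing (ring A) + OC stretching (methyl)
54	1079	1043		nu_CC	CC stretching (ring C) + CO stretching (ring C)
55	1088	1052		nu_CO	C-O stretching (methyl) + CCH bending (ring A) + CC stretching (ring C) + CCH bending (ring C)
56	1097	1061	1068	delta_CCH	CCH bending (ring A) + COH bending (ring A) + CO stretching (ring C)
57	1165	1127	1118	delta_CCH	CCH bending (ring B) + COH bending (ring B)
58	1167	1128		delta_CCH	CH rocking (methyl) (36) (ring A)
59	1172	1133		delta_COH	CCH bending (23) (ring B) + COH bending (11) (ring B)
60	1178	1139		delta_CCH	CCH bending (19) (ring A + C)
61	1189	1150	1151	delta_CCH	CCH + COH bending (15) (ring B)
62	1201	1161		delta_CCH	CCH bending (24) (ring A + C + B)
63	1208	1168		delta_COH	COH bending (ring A)
64	1215	1175		delta_COH	COH bending (19) (ring B)
65	1220	1180	1189	delta_CCH	CCH bending (21) (ring A + C)
66	1244	1203	1204	delta_CCH	CCH bending (28) (ring A + C + B)
67	1278	1236	1244	delta_HCH	CH wagging (19) (ring C)
68	1293	1250	1257	delta_CCH	CH bending (ring A) + OH bending (ring A) + ring breathing (ring A)
69	1314	1271	1271	delta_COH	COH bending (41) (ring B)
70	1345	1301	1302	delta_CCH	CH bending (ring C + ring B) + ring stretching (ring B)
71	1356	1311		delta_OCH	CH bending (19) (ring C)
72	1366	1321		nu_ring	ring stretching (ring A) + OCH bending (ring C) + ring stretching (ring B) + COH bending (ring B)
73	1372	1327	1331	delta_OCH	OCH bending (ring C) + COH bending (ring A) + COH bending (ring B)
74	1384	1338	1346	delta_OCH	OCH bending (ring C) + CO stretching (ring A) + methyl umbrella
75	1403	1357	1361	delta_CCH	CH bending (10) (ring C)
76	1454	1406	1407	delta_CCH	CH2 scissoring (22) (ring C)
77	1463	1415	1419	delta_CCH	methyl umbrella (24) + OCH bending (25) (ring A)
78	1477	1428	1436	delta_CCH	methyl umbrella (49)
79	1493	1444	1439	delta_HCH	HCH bending (methyl) (82) (ring A)
80	1502	1452	1450	delta_CCH	CCH bending (14) (ring B) + HCH bending (methyl) (10) (ring A)
81	1503	1453		delta_HCH	HCH bending (methyl) (24) (ring A) + COCH torsion (13) (ring A)
82	1521	1471		delta_CCH	CCH bending (17) (ring A) + OCH bending (10) (ring A)
83	1533	1482	1499	delta_CCH	CCH bending (23) (ring B) + ring stretching (12) (ring B)
84	1604	1551	1553	nu_ring	ring stretching (18) (ring B)
85	1645	1591	1559	nu_CC	CC stretching (11) (ring B)
86	1649	1595	1601	nu_CC	CC stretching (11) (ring A)
87	1660	1605		delta_CCH	CCH bending (19) (ring B) + CC stretching (12) (ring B)
88	1744	1686	1615	nu_C=O	C=O stretching (15) (ring C) + CC stretching (10) (ring C)
89	2997	2862	2851	nu_CH	CH stretching (52) (ring C)
90	3011	2876	2872	nu_CH	methyl symmetric stretching (79) (ring A-methyl)
91	3033	2897	2909	nu_CH	CH2 symmetric stretching (69) (ring C)
92	3073	2935	2944	nu_CH	methyl asymmetric stretching (81) (ring A-methyl)
93	3110	2970	2980	nu_CH	CH asymmetric stretching (58) (ring C)
94	3140	2999	2997	nu_CH	CH stretching (79) (ring B)
95	3152	3010		nu_CH	CH stretching (70) (ring B)
96	3175	3032	3023	nu_CH	CH stretching (74) (ring B)
97	3190	3046		nu_CH	CH stretching (71) (ring A)
98	3214	3069		nu_CH	CH stretching (73) (ring B)
99	3217	3072	3076	nu_CH	CH stretching (74) (ring A)
100	3818	3646		nu_OH	OH stretching (90) (ring A)
101	3835	3662		nu_OH	OH stretching (91) (ring B)
102	3836	3663		nu_OH	OH stretching (91) (ring B)
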