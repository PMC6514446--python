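SNP	Name	Change	PolymorphismType	Position	Coverage	VariantCoverage	GenomicDetected	TranscriptomeProportion	InDuplication	GenomicVariant1	GenomicTotal1	GenomicVariant2	GenomicTotal2
1	G	C -> G	SNP (transversion)	106	16	13	True	0.81	False	5.0	8.0	4.0	8.0
2	G	A -> G	SNP (transition)	150	19	8	True	0.42	False	1.0	8.0	2.0	8.0
3	C	G -> C	SNP (transversion)	246	34	7	True	0.21	False	1.0	8.0	2.0	8.0
4	T	A -> T	SNP (transversion)	369	65	7	True	0.11	False	1.0	8.0	2.0	8.0
5	A	G -> A	SNP (transition)	371	68	19	False	0.28	False	1.0	8.0	1.0	8.0
6	C	T -> C	SNP (transition)	390	64	15	False	0.23	False	1.0	8.0	1.0	8.0
7	G	T -> G	SNP (transversion)	513	46	12	True	0.26	False	3.0	8.0	4.0	8.0
8	A	G -> A	SNP (transition)	518	45	10	True	0.22	False	2.0	8.0	3.0	8.0
9	T	G -> T	SNP (transversion)	731	54	8	True	0.15	False	2.0	8.0	3.0	8.0
10	C	A -> C	SNP (transversion)	1008	56	9	False	0.16	False	1.0	8.0	1.0	8.0
11	T	C -> T	SNP (transition)	1061	91	29	True	0.32	False	2.0	8.0	3.0	8.0
12	T	C -> T	SNP (transition)	1088	77	41	True	0.53	False	4.0	8.0	3.0	8.0
13	T	C -> T	SNP (transition)	1190	76	9	True	0.12	False	2.0	8.0	3.0	8.0
14	A	G -> A	SNP (transition)	1209	76	20	False	0.26	False	1.0	8.0	1.0	8.0
15	T	A -> T	SNP (transversion)	1251	62	10	True	0.16	False	2.0	8.0	3.0	8.0
16	G	A -> G	SNP (transition)	1255	62	55	True	0.89	False	6.0	8.0	5.0	8.0
17		-ATG	Deletion	1307	75	9	True	0.12	False	1.0	8.0	2.0	8.0
18	G	A -> G	SNP (transition)	1314	90	23	True	0.26	False	1.0	8.0	2.0	8.0
19	G	T -> G	SNP (transversion)	1347	103	13	True	0.13	False	2.0	8.0	3.0	8.0
20	A	T -> A	SNP (transversion)	1384	101	37	True	0.37	False	1.0	8.0	2.0	8.0
21	G	C -> G	SNP (transversion)	1424	80	9	False	0.11	False	1.0	8.0	1.0	8.0
22	A	C -> A	SNP (transversion)	1437	84	10	True	0.12	False	1.0	8.0	2.0	8.0
23	TT	AA -> TT	Substitution	1481	62	7	False	0.11	False	1.0	8.0	1.0	8.0
24	G	A -> G	SNP (transition)	1527	106	90	True	0.85	True				
25	C	T -> C	SNP (transition)	1540	139	86	True	0.62	True				
26	A	T -> A	SNP (transversion)	1584	253	235	True	0.93	True				
27	A	G -> A	SNP (transition)	1638	247	39	True	0.16	True				
28	C	A -> C	SNP (transversion)	1648	209	106	True	0.51	True				
29	A	C -> A	SNP (transversion)	1739	122	16	True	0.13	True				
30	T	C -> T	SNP (transition)	1751	132	32	True	0.24	True				
31	A	G -> A	SNP (transition)	1753	138	16	True	0.12	True				
32	A	C -> A	SNP (transversion)	1762	131	21	False	0.16	True				
33	T	A -> T	SNP (transversion)	1776	125	75	True	0.6	True				
34	C	G -> C	SNP (transversion)	1796	88	31	False	0.35	True				
35	G	C -> G	SNP (transversion)	1808	37	25	True	0.68	False	4.0	7.0	4.0	7.0
36	T	C -> T	SNP (transition)	1808	78	41	True	0.53	True				
37	T	C -> T	SNP (transition)	1814	78	27	True	0.35	True				
38	T	C -> T	SNP (transition)	1827	68	7	True	0.1	True				
39	A	T -> A	SNP (transversion)	1830	65	8	True	0.12	True				
40	A	G -> A	SNP (transition)	1839	62	23	True	0.37	True				
41	A	G -> A	SNP (transition)	1853	52	6	True	0.12	True				
42	C	A -> C	SNP (transversion)	1866	47	30	True	0.64	True				
43	A	C -> A	SNP (transversion)	1910	152	34	True	0.22	True				
44	A	G -> A	SNP (transition)	1917	158	103	True	0.65	True				
45	G	T -> G	SNP (transversion)	1922	165	110	True	0.67	True				
46	T	A -> T	SNP (transversion)	1938	170	41	True	0.24	True				
47	A	C -> A	SNP (transversion)	2039	196	37	True	0.19	True				
48	T	C -> T	SNP (transition)	2043	196	143	True	0.73	True				
49	G	T -> G	SNP (transversion)	2080	177	88	True	0.5	True				
50	C	A -> C	SNP (transversion)	2123	126	89	True	0.71	True				
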