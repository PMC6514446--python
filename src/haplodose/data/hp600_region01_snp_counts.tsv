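SNP	Name	Change	PolymorphismType	Position	Coverage	VariantCoverage	GenomicDetected	TranscriptomeProportion	InDuplication	GenomicVariant1	GenomicTotal1	GenomicVariant2	GenomicTotal2
1	C	G -> C	SNP (transversion)	12	443	101	True	0.23	False	1	8	2	8
2	-	-C	Deletion	78	515	28	True	0.05	False	1	8	2	8
3	T	C -> T	SNP (transition)	133	542	38	True	0.07	False	1	8	2	8
4	A	G -> A	SNP (transition)	153	577	33	True	0.06	False	1	8	2	8
5	TT	GG -> TT	Substitution	166	699	137	True	0.2	False	1	8	2	8
6	T	C -> T	SNP (transition)	263	569	55	False	0.1	False	1	8	1	8
7		(GAG)3 -> (GAG)2	Deletion (tandem repeat)	283	654	42	False	0.06	False	1	8	1	8
8	C	T -> C	SNP (transition)	429	849	83	False	0.1	False	1	8	1	8
9	A	G -> A	SNP (transition)	434	993	69	False	0.07	False	1	8	1	8
10	C	G -> C	SNP (transversion)	436	1035	275	True	0.27	False	2	8	3	8
11	T	G -> T	SNP (transversion)	463	936	56	False	0.06	False	1	8	1	8
12	A	C -> A	SNP (transversion)	519	679	57	False	0.08	False	1	8	1	8
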