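# panel_name=synthetic81
# version=1
# coordinates are 0-based half-open
# locus_id	chrom	repeat_start	repeat_end	repeat_unit	ref_repeat_length	left_flank	right_flank	cancer_type_tags
ABCC5	chr19	25766594	25766607	A	13	AGTCCTACGGTCTCC	CCAGATATCGAAATT	UCEC
IMPDH1	chr19	129602725	129602749	T	24	TCCACGCCGAACGAC	GTCAAATCGCTTTTG	UCEC
GSE1	chr2	88212045	88212068	A	23	GGACAATGCGGTTGG	CCCCCCCTTTACGAA	UCEC
JAK1	chr13	52390328	52390342	T	14	CAGCTCGACTAAATA	AAGCGAGTCATCCCC	UCEC
JPH4	chr21	177445804	177445819	C	15	GCTTGAGCGCGGTGA	AAACACCCCGCCCAG	UCEC
CHD3	chr7	12741914	12741930	A	16	GTAAGGCGAGAGGCT	GACAAAGGGTGTATC	UCEC
BMPR2	chr14	97474405	97474416	A	11	AATGGTACTTTCAAT	GACATGACGGGTTGC	COAD
ELAV3	chr15	175442520	175442537	A	17	GCGTTATACGCCGCT	CGGGCGGACGGGAGC	COAD
GLYR1	chr15	16053039	16053063	A	24	TGTATCTGTCTCTTC	TAAAAGATTCAAGGC	COAD
ZNF43	chr22	93498390	93498411	T	21	ACGTTTCATATCTTC	CTCGACTGGTGTCAC	COAD
XYLT2	chr15	119673743	119673759	T	16	ATGATACCATGTGGC	GCCCTATGGATAACG	STAD
BAT25	chr10	157806397	157806416	T	19	GTGCGCCCAACGTTC	GAAAAGATGTGATGG	
BAT26	chr19	82601961	82601977	T	16	CCTTCGGACGCTCTG	AGCCAAGTGGTAAAA	
NR21	chr15	161387532	161387548	A	16	GACAGGGATCGGCGG	GCTTAAACGCAGGAG	
NR24	chr22	6563398	6563422	A	24	TACTTCATCGCTTAC	CTCTGTGGAAGACAG	
MONO27	chr6	21049446	21049467	A	21	ATAACCGCCCGTATT	CCTTTACTGCTCGAC	
ACVR2A	chr16	60927377	60927393	A	16	TTAGCACGTCGGACC	GTGTAGAATGTTATC	
TGFBR2	chr20	89026819	89026836	A	17	ACTGGATTTCGCTGG	TAGTACCGACACTCA	
ASTE1	chr2	94476454	94476478	G	24	ATACCGGACTATCCT	TCGTCTAATGACCTA	
SETD1B	chr19	158242142	158242156	T	14	CCCACATGTTTCAAC	ATGTTTAGTGTTACC	
RNF43	chr14	54495414	54495431	T	17	TGTACGTTAGGCTAC	GGATCGCGGTGTGGT	
MSH3	chr7	189959473	189959489	T	16	AATATCGTTATAGAG	CGTCTCTCTATCCGG	
BAX	chr18	147942624	147942648	T	24	GGTAATACTTCGGCA	GTGCCTGCAAAGAAC	
DOCK3	chr21	138135871	138135889	T	18	TCGATTAGTTGAAAG	GATAAACTCTGGGTG	
MBD4	chr22	152550089	152550099	T	10	GATAGCTCATAGGAA	ATGCCCAAAAAGAGC	
CTCF	chr11	137781453	137781468	T	15	TTCGGCAACTTGGGC	GGAATGGCTTTGATG	
KMT2B	chr19	150486434	150486448	T	14	GCGACGGATCTGAAA	GGTCAAGAAAGTAAA	
SRSF6	chr1	182866445	182866466	G	21	TGCGCGCGTTGAAAA	CTTGACTCCGAACGT	
CASP5	chr2	160304610	160304629	T	19	TCTCCCCTGGTGTAG	ATTCACGTTCGACGT	
TCF7L2	chr10	122676216	122676236	A	20	AACTGGAGACTAACT	TCTCCCGGGTTAGAA	
SEC31A	chr18	155258009	155258029	T	20	TGGACACGCCAGTTA	CGTCGGTCCCGGGTG	
PRDM2	chr8	108518955	108518966	T	11	AAGACAATATCAGAG	GACCAGTCGGGATTA	
RPL22	chr14	87215579	87215596	A	17	TTCAGGAGGACGAAC	GACAAAAGGCGCGCC	
ESRP1	chr19	3557253	3557277	A	24	GCAGTCAAATGTGGT	CCGTGCCACCGTATT	
LTN1	chr15	181567873	181567886	A	13	CGACGAATTCATTTG	GCCCTGAGGATACAG	
FAM111B	chr17	96119025	96119035	T	10	GTAGGGTTAAGAGGG	CGAATCGTGGCTTGG	
SPINK5	chr12	131770593	131770616	G	23	GCGATCTTTGATGGT	TACGTTATAGGGAAT	
SLC22A9	chr14	182843547	182843570	A	23	TACCTAACGTTGTTC	TGTTTCGTATGGCGT	
MYH11	chr1	93342853	93342870	T	17	CCAATCTCCGATATC	ACGCGAAATGCTCGG	
TMEM60	chr8	100739671	100739682	A	11	GCTGTAATACACAAC	GGAGGGTTACATTGA	
MS041	chr4	187204092	187204110	T	18	CAGGTTAACGAATTC	ATAATACTGGTGTAG	
MS042	chr16	119084415	119084429	T	14	GTAGCCCGTCGGTGA	GACGCAGGCCCCCAG	
MS043	chr10	11330745	11330759	T	14	TGACGTTTGGAGCAG	ATGTTATATCCAGTT	
MS044	chr5	13261870	13261894	T	24	GTAGCGGGTACCGTC	CTTTCAGGAGTTGGA	
MS045	chr13	108342554	108342565	A	11	GAGAGTAATCGACCT	CTATAAAAGCTAACC	
MS046	chr16	72037582	72037594	A	12	GTTAAAAGGTTGTCG	CTGTCAGTAACACTG	
MS047	chr2	176390360	176390372	T	12	TACTCCGCCACTTCG	CCAGGGTGGTGTCTG	
MS048	chr15	54509408	54509427	A	19	ATCAAAAGCTGCAGG	CTATTTAATGGCTGT	
MS049	chr1	123398305	123398328	T	23	GTTGGATGTACGGCG	AAGTCCGGAACCTGC	
MS050	chr16	147343818	147343829	T	11	CGTGACCAACATTAG	CCTAGTAGATTACAC	
MS051	chr1	195522765	195522787	A	22	ACTAACTCGCGGTCG	TGAAGAGGCTGGTCG	
MS052	chr17	136439988	136439998	A	10	ACCGAAATCTGACCC	TCTAACTCACGCGGT	
MS053	chr14	12878430	12878447	A	17	GCACGAGGTTGCATT	TCCCCCACGAGTACC	
MS054	chr2	198695004	198695014	T	10	GTCACATAACGTTAG	AGACTAACATTACCA	
MS055	chr3	100466126	100466143	A	17	AGGCAATACTGGGTT	GTCTGTTCAAGTTCA	
MS056	chr22	179401694	179401718	T	24	AGTTAAGGCTACCTG	GAATTGCGCGGCCTT	
MS057	chr5	56726692	56726712	A	20	CAATTACAGACTCAT	TTGTGTCGATTTACG	
MS058	chr18	34779284	34779303	A	19	GATCACCTGCTTATG	TACTTGAGTGAATAC	
MS059	chr8	52075838	52075854	A	16	CTGGCACTTTCCGTT	GGGGGCCTGACTTTT	
MS060	chr19	33984755	33984773	A	18	GACGCTCTGCGTTCT	TAGACACCGACCAAA	
MS061	chr13	135747380	135747397	A	17	TAGAGGCAGCCTCGT	TGCGAGGACGCGCTG	
MS062	chr16	192132171	192132191	A	20	CGCGATCGTACTTGT	TGGTAGTGTAAAGAC	
MS063	chr13	115608336	115608353	A	17	TCTCCAGAACCTTTC	GTCGGTACGAGCAAT	
MS064	chr1	159894586	159894604	A	18	ATAACTGAGGAGGTC	CAGCCGAAGAATGGA	
MS065	chr1	131181131	131181142	A	11	ACCCGGGCATGCCGT	TGCTTCCCCTTCCAT	
MS066	chr11	62920975	62920991	A	16	TTAAACACTACAGTC	GGAAGGGCTTCATGA	
MS067	chr8	40018739	40018751	A	12	GAACCTCCTCTACTC	GGTTTTAGGCTCAAC	
MS068	chr11	118897396	118897406	A	10	AGGGAATTGCAAAAT	CTGAGTACGGGTCCC	
MS069	chr8	108311323	108311336	A	13	GCGGTCTATGCACAG	TAAACCAATTAATCG	
MS070	chr3	23550933	23550943	A	10	TGAGACTTAGGCAAT	TAATATCCAGCGGTA	
MS071	chr11	102343999	102344016	T	17	CGGTCTAGGCATCTG	GCAGCACCCCTCGGC	
MS072	chr9	169939345	169939355	A	10	CTCTGACATAAACCG	CTCAGTAATGGGCGG	
MS073	chr12	139228957	139228975	A	18	TACGTAGAGGATCGT	GCGAGAGTTTTGGTT	
MS074	chr22	161299981	161299993	A	12	CCCTACGCGCGTCCC	TATTGCGGCGATACC	
MS075	chr12	19136623	19136634	A	11	GATTATAACTGCATG	TCCGCTTTCACTGGT	
MS076	chr18	17747504	17747517	G	13	GGCTAGCTGGTCCGT	TGCTTGACAATTGTG	
MS077	chr11	1107856	1107872	A	16	TTTCCACCATCGCGG	TCACTCAAGGGCCCT	
MS078	chr4	145720653	145720666	A	13	CCTCGACTCCAAGTT	CAAGAAGTCGAAAAA	
MS079	chr15	51221097	51221118	T	21	GCGTGCCCCATTGAC	CGTTTGCATTCCTCC	
MS080	chr18	34215296	34215320	T	24	GTTTACAGCATTAAC	GCAGCGTATATGGAT	
MS081	chr15	75473373	75473395	T	22	AGTCCGGAATAAACA	AAACCAGCCTCCCGG	
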