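section	gene	pair	forward	reverse	product_bp	t3_extension_bp	incubation_p0_p7_h	incubation_p14_p22_h	usage	rtpcr_negative
3utr	Ankrd13b	3utr	TCCAAGGGCGGAGGCAGGTA	TCAGGGAAGGGAAGAGGAAG	821	26	5	6	both	no
3utr	Cdh4	3utr	AAGTCCCAGCACTGATGAAA	AACACCACCCGAATTGTTTGC	501	26	6	6	both	no
3utr	Elfn1	3utr	CCTGCGCAAGAAGGTTCAGT	TCTTGCTTGCTTGCACCAGGC	367	26	6	6	both	no
3utr	Eml1	3utr	CACTGTGATTTCTGTTTTGTC	TAGCCAGCCTCCCAAAGGGAG	473	26	6	3	both	no
3utr	Fam19a4	3utr	AACTTTATGAACCTTGGAGAATG	TGAAATTGGAGGCAAGATGACT	498	26	6	3	both	no
3utr	Foxp2	3utr	CTGTGCTGTTAGTGTAAAGATGT	GTTGCTTTCTAGAGTGTCATAAC	503	26	3	3	both	no
3utr	Gabra1	3utr	GTTCTTTTAGTCGTATTCTGTTGG	AGCTTGCAAAATAGATTTGCC	900	26	6	6	both	no
3utr	Grm4	3utr	GCCACACAGGCCTTCCTTCC	CTTCGAAACACACTCAAGATTAG	433	26	6	5	both	no
3utr	Hpca	3utr	CCTCTCCCTCGTGTCTATCC	GAGCTGGGACAAGAAGTGTTC	443	26	6	3	both	no
3utr	Plppr3	3utr	CAGTGCCAGCTCCGACTCTT	TTGCCAGGCTTAGTCCTGGTA	469	26	6	6	both	no
3utr	Mapk10	3utr	GTCACAACGCACTCACGAAA	GATCTGTATCTACATCCATCTGAC	364	26	6	5	both	no
3utr	Nptx1	3utr	GGGGCTGAGAGCTCACTTGA	CCACTTCGAGCCACGCTC	600	26	6	5	both	no
3utr	Nptx2	3utr	TCTCCGTCCCAGAGGCCACC	AGTTCCCTCAGACGGAAAG	486	26	6	6	both	no
3utr	Ntrk1	3utr	ATCGAGTGTATCACGCAGGGC	TATGATGGATGCTGGCCATGAA	328	26	6	5	both	no
3utr	Pcdh20	3utr	GACGAGTTTCCTACTTCTTGGG	TTATCGTTGATGTCCAGAAGAAG	511	26	6	9	both	no
3utr	Pick1	3utr	ACCACTGTAGGACAGCGAAGG	TTATTCAATACAGGCCCAGCTTC	393	26	6	9	both	no
3utr	Pip5kl1	3utr	ACAAGGTGTGTCGAAGTCGAA	GTAAGGGTTGGGGTCAGGGTC	458	26	6	6	both	no
3utr	Pnkd	3utr	CTTCACCATCCTCTTCATCAC	TGAAGGTGGAAGATAGACTAGCC	360	26	6	6	both	no
3utr	Rims1	3utr	CACCCTCCTCTGGAGTCCAG	TGTGTCTGCAGTTTATACCAATG	500	26	2	3	both	no
3utr	Tmem25	3utr	TGCCTGTCCCTGTTGTGACC	GTACAAAACGATGCAGAGCTAC	687	26	6	6	both	no
3utr	Tmem91	3utr	CAACAAGGCTTGGGCCAAGG	GGGTATCTTTAATTTCTCACATTG	348	26	6	5	both	no
3utr	Tshz2	3utr	GCAGAAAGAAAGGGAAATATGTG	CATCACCTATTTGTTCTCTTCG	418	26	6	6	both	no
3utr	Tusc5	3utr	CTGGAGATCTCCGAACCTACA	TATGGAGGATTTCCGTATGGCC	492	26	6	5	both	no
3utr	Pou4f1	3utr	TGTGTAGAAGATCCCCTTTG	GGCACAGAAATGGTTCTGATG	519	26	3	3	both	no
transcript_specific	Clcc1	pr.1+pr.9	CACAGCTGCGGGCCGAGC	CTGAGATTTCCTCATCGTTCCT	208	26	na	na	rtpcr_only	no
transcript_specific	Clcc1	pr.2+pr.9	AGTCCGCTCGGGACTCCAG	CTGAGATTTCCTCATCGTTCCT	181/252	26	7	7	both	no
transcript_specific	Clcc1	pr.3+pr.9	TGTTTGAGGTAGGCGGCTCG	CTGAGATTTCCTCATCGTTCCT	220	26	na	na	rtpcr_only	no
transcript_specific	Clcc1	pr.4+pr.9	TCGGCGTCTTCCGCGGCC	CTGAGATTTCCTCATCGTTCCT	203	26	na	na	rtpcr_only	no
transcript_specific	Clcc1	pr.5+pr.9	TCCCTCTGAAAGAGCAGGCAG	CTGAGATTTCCTCATCGTTCCT	172	26	na	na	rtpcr_only	no
transcript_specific	Clcc1	pr.6+pr.9	TGAGTGGGCGCTCTTCGGTG	CTGAGATTTCCTCATCGTTCCT	293	26	na	na	rtpcr_only	yes
transcript_specific	Clcc1	pr.7+pr.9	CGTTTCCAGGATACACCGAGA	CTGAGATTTCCTCATCGTTCCT	300	26	na	na	rtpcr_only	no
transcript_specific	Clcc1	pr.2+pr.8	AGTCCGCTCGGGACTCCAG	CGGGTTAAGGGAAGTCAAATTC	199/270	26	na	na	rtpcr_only	yes
transcript_specific	Clcc1	pr.7+pr.8	CGTTTCCAGGATACACCGAGA	CGGGTTAAGGGAAGTCAAATTC	159	26	4	3	ish_only	no
transcript_specific	Clcc1	pr.10+pr.11	GTGAGGTCTGGAACATCAGAG	CATAAACACATTATATGGATCTA	432	26	na	na	rtpcr_only	no
transcript_specific	Pnkd	pr.1+pr.2	TGGGACCCGAACATGGCGGG	GCTAGCCCCACGGCTTTC	246	26	2	3	both	no
transcript_specific	Pnkd	pr.3+pr.4	TGTGGTATCCTCTTCTTCGTC	CTCCTTCCACGGTGTGGAAG	289	26	2	3	both	yes
transcript_specific	Pnkd	pr.5+pr.6	CCCAGCATGGCTTGGCAGG	CCGATTCGGAAGAGCAGCCG	167	26	2	3	both	no
transcript_specific	Pnkd	pr.5+pr.7	CCCAGCATGGCTTGGCAGG	ATTGAAGAGGCGGGGCTGAG	282	26	na	na	rtpcr_only	no
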