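mature_seq	seed	predominant_arm	reads_5p	reads_3p	conservation_note	low_confidence	fields_ambiguous
GUCGACAGAGAGAUAAAUCACU	UCGACAG	3p	5649	207160	aae-miR-2940	0	0
UGUUAACUGUAAGACUGUGUCU	GUUAACU	3p	17	76143	aae-miR-999	0	0
CUAAGUACUAGUGCCGCAGGAG	UAAGUAC	5p	63196	396	aae-miR-252	0	0
UAGCACCAUUCGAAAUCAGUAC	AGCACCA	3p	63	8597	aae-miR-285	0	0
UCAAUUCCGUAGUGCAUUGCAGU	CAAUUCC	5p	3981	39	aae-miR-932	0	0
GUAGGCCGGCGGAAACUACUUGC	UAGGCCG	3p	10	2313	bmo-miR-2796	0	0
UGACUAGAGGCAGACUCGUUUG	GACUAGA	3p	195	1637	aae-miR-2945	0	0
UAGCACCAUGAGAUUCAGCUC	AGCACCA	3p	86	1674	aae-miR-998	0	0
UGACUAGACCGAACACUCGUAUC	GACUAGA	3p	4	503	aae-miR-286b	0	0
UUGGUGUUAUAUCUUACAGUGAG	UGGUGUU	3p	1	597	dme-miR-971	0	0
GAAGGAACUUCUGCUGUGAUCU	AAGGAAC	5p	142	7	aae-miR-2944a	0	0
GAAGGAACUCCCGGUGUGAUAUG	AAGGAAC	5p	104	21	aae-miR-2944b	0	0
UAUCACAGCCAGCUUUGAAGA	AUCACAG	3p	1858	25519	aae-miR-2a	0	0
UGGCAAGAUGUUGGCAUAGCU	GGCAAGA	5p	24655	180	aae-miR-31	0	0
AUUAGAAUGUGGAAUCUGUUUUU	UUAGAAU	5p	1572	803	hsa-miR-561 seed, conserved in aae, cqu	0	0
UGAACACCCAUUUAUUGCCGACAGG	GAACACC	3p	12	1341	miR conserved in aae, miR-N3	0	0
CCCUGUGGAACACCAUGUACGAUGG	CCUGUGG	3p	0	202	bmo-miR-3389 seed, conserved in aae	0	0
CAGUACUUCUGCAAUGCAACCC	AGUACUU	3p	113	1577	aae-miR-33	0	0
AUGGAUUCGAUCGAUCGAGUGC	UGGAUUC	5p	236	48	dme-miR-976 seed	0	0
UAGUACGAAUACGUACGAGGGA	AGUACGA	3p	17	61	aae-miR-2946 seed	0	0
UGUGGUGGCACACUUUGACAAC	GUGGUGG	3p	2	15	tca-miR-3897 seed	0	0
AAUGGCACUCUUGUUGGACAAG	AUGGCAC	5p	24	2	aae-miR-263a seed	0	0
UUAUACUUCCUGCUUCACCGAU	UAUACUU	3p	0	120	aae-miR-305 seed	0	0
GAUUUGUCCAAAAAGGAUG	AUUUGUC	3p	0	14	aae-miR-981	0	0
AGGAUUACGAUGAAGUGUUUGCGCC	GGAUUAC	5p	135	0	bmo-miR-2846 seed, conserved in aae	0	0
AGAAAGACAUGGGUAGUGAGAU	GAAAGAC	3p	1512	13384	aae-mir-71	0	0
ACACGAUAAGAGGAAAGUUUACG	CACGAUA	5p	79	11	No, miR-N1a	0	0
UUAGAUUCCCAGAUCGUCAGAU	UAGAUUC	3p	1	48	hsa-miR-376a seed	0	0
UAAGUGCAAAUCGUUGUAGUCGGUU	AAGUGCA	5p	449	0	hsa-miR-519b seed, miR-N6	0	0
UUGACUGUCGCCUCUGCGGAUG	UGACUGU	5p	103	0	hsa-miR-943 seed	0	0
UUGGAGAUCAAAAGACGAUGUUUUU	UGGAGAU	5p	20	2	hsa-miR-1270 seed	0	0
AUGGGGUUUGACCUGCUGGGC	UGGGGUU	5p	41	0	hsa-miR-3170 seed	0	0
CGGGCUGUUGCAGCAGGUGCCU	GGGCUGU	3p	0	67	hsa-miR-4741 seed	0	0
GUAGUCCGGAGUGGAGUC	UAGUCCG	5p	30	0	hsa-miR-6723 seed	0	0
AACGAGUUUCCCGAUACGACUG	ACGAGUU	5p	282	4	No	0	0
CAUUACCGAUGGAUCCUUACCG	AUUACCG	5p	187	28	No, miR-N2	0	0
UGCAUUCAGUGGGGCGGUCGU	GCAUUCA	3p	1	103	No	0	0
UAGACGAUUUCGGAAUGGCACAUCC	AGACGAU	3p	5	492	No	0	0
CCGGUGAACUGCUGUGCAGGGGCGC	CGGUGAA	3p	3	209	No	0	0
UCCGGCUACCGACUAACGGCUC	CCGGCUA	3p	2	68	No	0	0
ACUCCGGUCGACUCUGGACGAC	CUCCGGU	3p	11	34	No	0	0
UUGCGAGAGGACCUAUAAUGACU	UGCGAGA	5p	35	0	No	0	0
UUUUGGAACACAAGCUCGGCAGGCC	UUUGGAA	3p	0	241	No	0	0
AAUUGGACUCUAUAGCACCCU	AUUGGAC	3p	3	78	No	0	0
AACCGACAGAUCAUUGGCCAGA	ACCGACA	3p	0	2243	No	0	0
AGGAUUCGUAGUGCUACUGUGCAGA	GGAUUCG	5p	249	1	No	0	0
UACUUUCGCAAAUAGAUCGCUGCCU	ACUUUCG	5p	617	2	No, miR-N5	0	0
UUGGUCUGAUUGCCUACACUGGCUU	UGGUCUG	5p	497	4	No	0	0
UAGGAUCUAUUGACAUUGCAGCCU	AGGAUCU	5p	145	0	No	0	0
CUCGCUGGCUGUCCGCAAACU	UCGCUGG	3p	12	62	No	0	0
UGAGAGAACGAAAGCAUUCCUU	GAGAGAA	3p	1	34	No	0	0
AAUUGGACUCUGUGGCACCCU	AUUGGAC	5p	62	0	No	0	0
CGCUCGACUAUUUAUCGCCCGAGA	GCUCGAC	3p	2	252	No	0	0
CGAUACACGAACUGGGGCUCUCUCC	GAUACAC	3p	49	139	dme-miR-318 seed	1	1
UUGAAUUACGUCGGCAAUUUUUGGG	UGAAUUA	3p	25	18	hsa-miR-183 seed, miR-N4	1	1
UCUCCGUGGACGGCUGUCGAUGCC	CUCCGUG	5p	148	1	hsa-miR-3605 seed	1	1
UAGGCCCGACCAGAACUCGCUG	AGGCCCG	3p	0	12	hsa-miR-4747 seed	1	1
ACGAGGCGAAGACUUUGUUGCC	CGAGGCG	3p	2	12	No	1	1
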