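#glycomine-catalog	monomers	v1
id	name	smiles	reactive_groups	required_gene_classes	is_primary
p_glucose	D-glucose	OCC1OC(O)C(O)C(O)C1O	activated-anomeric:6;hydroxyl:1;hydroxyl:8;hydroxyl:10;hydroxyl:12	-	1
p_mannose	D-mannose	OCC1OC(O)C(O)C(O)C1O	activated-anomeric:6;hydroxyl:1;hydroxyl:8;hydroxyl:10;hydroxyl:12	-	1
p_glucosamine	D-glucosamine	NC1C(O)C(O)C(CO)OC1O	activated-anomeric:12;amine:1;hydroxyl:4;hydroxyl:6;hydroxyl:9	-	1
p_nacetylglucosamine	N-acetyl-D-glucosamine	CC(=O)NC1C(O)C(O)C(CO)OC1O	activated-anomeric:15;hydroxyl:7;hydroxyl:9;hydroxyl:12	-	1
p_xylose	D-xylose	OC1OCC(O)C(O)C1O	activated-anomeric:1;hydroxyl:6;hydroxyl:8;hydroxyl:10	-	1
p_ribose	D-ribose	OCC1OC(O)C(O)C1O	activated-anomeric:6;hydroxyl:1;hydroxyl:8;hydroxyl:10	-	1
s_streptidine	streptidine	OC1C(NC(=N)N)C(O)C(NC(=N)N)C(O)C1O	hydroxyl:1;hydroxyl:9;hydroxyl:16;hydroxyl:18	gc16;gc17;gc18;gc19;gc20	0
s_dihydrostreptose	dihydrostreptose	OC1OC(C)C(O)(CO)C1O	activated-anomeric:1;hydroxyl:11;hydroxyl:9	gc01;gc02;gc06;gc07	0
s_nmethylglucosamine	N-methyl-L-glucosamine	CNC1C(O)C(O)C(CO)OC1O	activated-anomeric:13;amine:2;hydroxyl:5;hydroxyl:7;hydroxyl:10	gc21;gc22;gc23	0
s_deoxystreptamine	2-deoxystreptamine	NC1CC(N)C(O)C(O)C1O	amine:1;amine:5;hydroxyl:7;hydroxyl:9;hydroxyl:11	gc12;gc13;gc14;gc15	0
s_kanosamine	kanosamine	OCC1OC(O)C(O)C(N)C1O	activated-anomeric:6;hydroxyl:1;hydroxyl:8;amine:10;hydroxyl:12	gc01;gc09;gc11	0
s_neosamine	neosamine C	NCC1OC(O)C(N)C(O)C1O	activated-anomeric:6;amine:1;amine:8;hydroxyl:10;hydroxyl:12	gc11;gc12	0
s_garosamine	garosamine	CNC1C(O)C(O)OCC1(C)O	activated-anomeric:7;amine:2;hydroxyl:5	gc02;gc29;gc34	0
s_purpurosamine	purpurosamine	NCC1CCC(N)C(O)O1	activated-anomeric:9;amine:1;amine:7	gc02;gc03;gc12	0
s_sisosamine	sisosamine	NCC1=CCC(N)C(O)O1	activated-anomeric:9;amine:1;amine:7	gc02;gc12;gc35	0
s_actinamine	actinamine	CNC1C(O)C(NC)C(O)C(O)C1O	amine:2;amine:7;hydroxyl:5;hydroxyl:10;hydroxyl:12;hydroxyl:14	gc16;gc17;gc28	0
s_actinospectose	actinospectose	CC1OC(O)C(=O)C(=O)C1O	activated-anomeric:5;ketone:6;ketone:8;hydroxyl:11	gc01;gc02;gc27	0
s_kasugamine	kasugamine	CC1OC(O)C(N)CC1N	activated-anomeric:5;amine:7;amine:10	gc02;gc27;gc36	0
s_fortamine	fortamine	CNC1C(O)C(O)C(N)C(O)C1OC	amine:2;amine:9;hydroxyl:5;hydroxyl:7;hydroxyl:11	gc30	0
s_streptamine	streptamine	NC1C(O)C(N)C(O)C(O)C1O	amine:1;amine:6;hydroxyl:4;hydroxyl:8;hydroxyl:10;hydroxyl:12	gc16;gc17	0
s_valienone	valienone	OCC1=CC(=O)C(O)C(O)C1O	ketone:5;hydroxyl:1;hydroxyl:8;hydroxyl:10;hydroxyl:12	gc24;gc25;gc26	0
s_aminodideoxyglucose	4-amino-4,6-dideoxy-D-glucose	CC1OC(O)C(O)C(O)C1N	activated-anomeric:5;hydroxyl:7;hydroxyl:9;amine:11	gc01;gc02;gc10	0
s_mycarose	D-mycarose	CC1OC(O)CC(C)(O)C1O	activated-anomeric:5;hydroxyl:11	gc01;gc02;gc03;gc04;gc05	0
s_olivose	D-olivose	CC1OC(O)CC(O)C1O	activated-anomeric:5;hydroxyl:8;hydroxyl:10	gc01;gc02;gc03;gc05	0
s_rhamnose	L-rhamnose	CC1OC(O)C(O)C(O)C1O	activated-anomeric:5;hydroxyl:7;hydroxyl:9;hydroxyl:11	gc01;gc02;gc07;gc08	0
s_evernitrose	evernitrose	CC1OC(O)CC(C)(NO)C1OC	activated-anomeric:5	gc02;gc03;gc04;gc33	0
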