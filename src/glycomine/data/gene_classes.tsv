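#glycomine-catalog	gene_classes	v1
id	name	hmm_ref	monomer_roles	modification_roles
gc01	NDP-glucose synthase (nucleotidyltransferase)	HMM_gc01	s_dihydrostreptose;s_kanosamine;s_actinospectose;s_aminodideoxyglucose;s_mycarose;s_olivose;s_rhamnose	-
gc02	NDP-glucose 4,6-dehydratase	HMM_gc02	s_dihydrostreptose;s_garosamine;s_purpurosamine;s_sisosamine;s_actinospectose;s_kasugamine;s_aminodideoxyglucose;s_mycarose;s_olivose;s_rhamnose;s_evernitrose	-
gc03	NDP-hexose 2,3-dehydratase	HMM_gc03	s_purpurosamine;s_mycarose;s_olivose;s_evernitrose	-
gc04	NDP-hexose 3-C-methyltransferase	HMM_gc04	s_mycarose;s_evernitrose	-
gc05	NDP-hexose 3-ketoreductase	HMM_gc05	s_mycarose;s_olivose	-
gc06	dTDP-dihydrostreptose synthase	HMM_gc06	s_dihydrostreptose	-
gc07	NDP-hexose 3,5-epimerase	HMM_gc07	s_dihydrostreptose;s_rhamnose	-
gc08	NDP-4-keto-hexose 4-ketoreductase	HMM_gc08	s_rhamnose	-
gc09	NDP-hexose 3-aminotransferase	HMM_gc09	s_kanosamine	-
gc10	NDP-hexose 4-aminotransferase	HMM_gc10	s_aminodideoxyglucose	-
gc11	hexose oxidoreductase	HMM_gc11	s_kanosamine;s_neosamine	-
gc12	hexose 6-aminotransferase	HMM_gc12	s_deoxystreptamine;s_neosamine;s_purpurosamine;s_sisosamine	-
gc13	2-deoxy-scyllo-inosose synthase	HMM_gc13	s_deoxystreptamine	-
gc14	2-deoxy-scyllo-inosose aminotransferase	HMM_gc14	s_deoxystreptamine	-
gc15	2-deoxy-scyllo-inosamine dehydrogenase	HMM_gc15	s_deoxystreptamine	-
gc16	myo-inositol dehydrogenase	HMM_gc16	s_streptidine;s_actinamine;s_streptamine	-
gc17	scyllo-inosose aminotransferase	HMM_gc17	s_streptidine;s_actinamine;s_streptamine	-
gc18	amidinotransferase	HMM_gc18	s_streptidine	mod13;mod30
gc19	scyllo-inosamine kinase	HMM_gc19	s_streptidine	-
gc20	inosamine-phosphate amidinotransferase	HMM_gc20	s_streptidine	-
gc21	NDP-hexose 2-isomerase	HMM_gc21	s_nmethylglucosamine	-
gc22	hexosamine N-methyltransferase	HMM_gc22	s_nmethylglucosamine	-
gc23	NDP-hexose C3 oxidoreductase	HMM_gc23	s_nmethylglucosamine	-
gc24	2-epi-5-epi-valiolone synthase	HMM_gc24	s_valienone	-
gc25	C7-cyclitol kinase	HMM_gc25	s_valienone	-
gc26	C7-cyclitol dehydratase	HMM_gc26	s_valienone	-
gc27	NDP-hexose 4-ketoisomerase	HMM_gc27	s_actinospectose;s_kasugamine	-
gc28	aminocyclitol N,N-dimethyltransferase	HMM_gc28	s_actinamine	-
gc29	NDP-hexose 4-C-methyltransferase	HMM_gc29	s_garosamine	-
gc30	aminocyclitol O-methyltransferase	HMM_gc30	s_fortamine	-
gc31	glycosyltransferase family 4	HMM_gc31	-	-
gc32	glycosyltransferase family 1	HMM_gc32	-	-
gc33	nitro-sugar N-oxidase	HMM_gc33	s_evernitrose	mod34
gc34	hexosamine 3-N-methyltransferase	HMM_gc34	s_garosamine	-
gc35	NDP-sugar 4,5-desaturase	HMM_gc35	s_sisosamine	-
gc36	hexose 2,4-diaminotransferase	HMM_gc36	s_kasugamine	-
gc37	tailoring O-methyltransferase	HMM_gc37	-	mod01;mod22;mod29;mod36;mod43
gc38	tailoring N-methyltransferase	HMM_gc38	-	mod02;mod27;mod44
gc39	tailoring C-methyltransferase	HMM_gc39	-	mod03;mod28;mod42;mod46
gc40	tailoring O-acyltransferase	HMM_gc40	-	mod04;mod38
gc41	tailoring N-acyltransferase	HMM_gc41	-	mod05;mod23;mod37;mod41
gc42	tailoring carbamoyltransferase	HMM_gc42	-	mod14;mod26
gc43	tailoring phosphotransferase	HMM_gc43	-	mod16
gc44	tailoring sulfotransferase	HMM_gc44	-	mod15
gc45	tailoring oxidoreductase	HMM_gc45	-	mod06;mod07;mod08;mod11;mod12;mod17;mod18;mod19;mod21;mod31;mod39;mod40;mod45;mod47;mod48;mod49
gc46	tailoring aminotransferase	HMM_gc46	-	mod09;mod12;mod48
gc47	tailoring dehydratase	HMM_gc47	-	mod10;mod11;mod17;mod19;mod35
gc48	halogenase	HMM_gc48	-	mod25;mod42
gc49	radical SAM epimerase	HMM_gc49	-	mod20
gc50	flavin-dependent monooxygenase	HMM_gc50	-	mod24;mod32;mod33;mod34;mod36;mod37
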