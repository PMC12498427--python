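#glycomine-catalog	modifications	v1
id	name	enzyme_gene_classes	motif_smiles	commands	mass_delta
mod01	O-methylation of hydroxyl	gc37	CO	add 3 C;connect 2 3 1	14.0157
mod02	N-methylation of amine	gc38	CN	add 3 C;connect 2 3 1	14.0157
mod03	C-methylation at carbinol carbon	gc39	CO	add 3 C;connect 1 3 1	14.0157
mod04	O-acetylation of hydroxyl	gc40	CO	add 3 C;add 4 C;add 5 O;connect 2 3 1;connect 3 4 1;connect 3 5 2	42.0106
mod05	N-acetylation of amine	gc41	CN	add 3 C;add 4 C;add 5 O;connect 2 3 1;connect 3 4 1;connect 3 5 2	42.0106
mod06	oxidation of secondary alcohol to ketone	gc45	CC(O)C	connect 2 3 2	-2.0157
mod07	oxidation of primary alcohol to aldehyde	gc45	OCC	connect 1 2 2	-2.0157
mod08	oxidation of primary alcohol to carboxylate	gc45	OCC	add 4 O;connect 2 4 2	13.9793
mod09	transamination of carbonyl to amine	gc46	C=O	disconnect 1 2;remove 2;add 3 N;add 4 H;add 5 H;connect 3 4 1;connect 3 5 1;connect 1 3 1	1.0316
mod10	4,6-dehydration of glycol terminus	gc47	C(CO)O	disconnect 2 3;remove 3;connect 1 4 2	-18.0106
mod11	deoxygenation of hydroxyl	gc45;gc47	CO	disconnect 1 2;remove 2	-15.9949
mod12	hydroxyl-to-amine exchange	gc45;gc46	CO	disconnect 1 2;remove 2;add 3 N;connect 1 3 1	-0.9840
mod13	guanidination of amine	gc18	CN	add 3 C;add 4 N;add 5 N;connect 2 3 1;connect 3 4 2;connect 3 5 1	42.0218
mod14	O-carbamoylation	gc42	CO	add 3 C;add 4 O;add 5 N;connect 2 3 1;connect 3 4 2;connect 3 5 1	43.0058
mod15	O-sulfation	gc44	CO	add 3 S;add 4 O;add 5 O;add 6 O;connect 2 3 1;connect 3 4 2;connect 3 5 2;connect 3 6 1	79.9568
mod16	O-phosphorylation	gc43	CO	add 3 P;add 4 O;add 5 O;add 6 O;connect 2 3 1;connect 3 4 2;connect 3 5 1;connect 3 6 1	79.9663
mod17	ring desaturation	gc45;gc47	CC	connect 1 2 2	-2.0157
mod18	ketoreduction	gc45	CC(C)=O	connect 2 4 1	2.0157
mod19	vicinal-diol dideoxygenation to alkene	gc45;gc47	OCCO	disconnect 1 2;remove 1;disconnect 3 4;remove 4;connect 2 3 2	-34.0055
mod20	epimerization (2D identity)	gc49	CO	-	0.0000
mod21	oxidative deamination of amine to ketone	gc45	CN	disconnect 1 2;remove 2;add 3 O;connect 1 3 2	-1.0316
mod22	carboxyl O-methylation (ester)	gc37	OC=O	add 4 C;connect 1 4 1	14.0157
mod23	N-formylation	gc41	CN	add 3 C;add 4 O;connect 2 3 1;connect 3 4 2	27.9949
mod24	C-hydroxylation	gc50	C	add 2 O;connect 1 2 1	15.9949
mod25	chlorination	gc48	C	add 2 Cl;connect 1 2 1	33.9610
mod26	N-carbamoylation	gc42	CN	add 3 C;add 4 O;add 5 N;connect 2 3 1;connect 3 4 2;connect 3 5 1	43.0058
mod27	N,N-dimethylation	gc38	CN	add 3 C;add 4 C;connect 2 3 1;connect 2 4 1	28.0313
mod28	C-methylation at amine-bearing carbon	gc39	CN	add 3 C;connect 1 3 1	14.0157
mod29	O-methylation of primary alcohol	gc37	OCC	add 4 C;connect 1 4 1	14.0157
mod30	amidination of aminocyclitol	gc18	NC1CCCCC1	add 8 C;add 9 N;add 10 N;connect 1 8 1;connect 8 9 2;connect 8 10 1	42.0218
mod31	anomeric oxidation to lactone	gc45	OC1OCCCC1	connect 1 2 2	-2.0157
mod32	epoxidation of alkene	gc50	C=C	add 3 O;connect 1 3 1;connect 2 3 1;connect 1 2 1	15.9949
mod33	N-hydroxylation	gc50	CN	add 3 O;connect 2 3 1	15.9949
mod34	N,N-dihydroxylation (nitro precursor)	gc50;gc33	CN	add 3 O;add 4 O;connect 2 3 1;connect 2 4 1	31.9898
mod35	dehydration of alcohol to alkene	gc47	CCO	disconnect 2 3;remove 3;connect 1 2 2	-18.0106
mod36	oxidative methoxylation	gc50;gc37	C	add 2 O;add 3 C;connect 1 2 1;connect 2 3 1	30.0106
mod37	N-glycolylation	gc41;gc50	CN	add 3 C;add 4 O;add 5 C;add 6 O;connect 2 3 1;connect 3 4 2;connect 3 5 1;connect 5 6 1	58.0055
mod38	O-propionylation	gc40	CO	add 3 C;add 4 O;add 5 C;add 6 C;connect 2 3 1;connect 3 4 2;connect 3 5 1;connect 5 6 1	56.0262
mod39	decarboxylation	gc45	CC(O)=O	disconnect 1 2;remove 3;remove 4;remove 2	-43.9898
mod40	reduction of aldehyde to alcohol	gc45	O=CC	connect 1 2 1	2.0157
mod41	O-glycylation (glycyl ester)	gc41	CO	add 3 C;add 4 O;add 5 C;add 6 N;connect 2 3 1;connect 3 4 2;connect 3 5 1;connect 5 6 1	57.0215
mod42	thiomethylation	gc39;gc48	C	add 2 S;add 3 C;connect 1 2 1;connect 2 3 1	45.9877
mod43	O-methylation of anomeric hydroxyl	gc37	OC1OCCCC1	add 8 C;connect 1 8 1	14.0157
mod44	N-methylation of guanidine	gc38	NC(=N)N	add 5 C;connect 1 5 1	14.0157
mod45	dehydrogenation of amine to imine	gc45	CN	connect 1 2 2	-2.0157
mod46	hydroxymethylation	gc39	C	add 2 C;add 3 O;connect 1 2 1;connect 2 3 1	30.0106
mod47	reduction of carboxyl to aldehyde	gc45	OC=O	disconnect 1 2;remove 1	-15.9949
mod48	terminal alcohol amination	gc45;gc46	OCC	disconnect 1 2;remove 1;add 4 N;connect 2 4 1	-0.9840
mod49	oxidative demethylation	gc45	CC	disconnect 1 2;remove 1	-14.0157
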