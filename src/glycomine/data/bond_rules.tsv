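#glycomine-catalog	bond_rules	v1
id	reaction_name	donor_group_type	acceptor_group_type	leaving_composition	bond_order
bond_glycosylation	glycosylation	activated-anomeric	hydroxyl	H2O	1
bond_n_glycosylation	dehydration	activated-anomeric	amine	H2O	1
bond_amidation	amidation	carboxyl	amine	H2O	1
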