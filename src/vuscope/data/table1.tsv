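family_id	genotype_cdna	classification	age_at_diagnosis	tumor_phenotype	bilateral	other_tumors	bc_fdr	bc_sdr	other_family_tumors	sex
1	c.349A>G	P/LP	62	Triple-negative	No	No	1	0	Renal	F
2	c.349A>G	P/LP	64	Luminal B	No	No	1	0	Pancreatic and ovarian	F
3	c.507delT	P/LP	56	Her2+	No	No	1	1	Ovarian and endometrium	F
4	c.844C>G	VUS	45	Luminal A	No	No	1	0	Prostate	F
5	c.1033C>T	VUS	38	Luminal B	No	No	1	0	Pancreatic, melanoma, and endometrium	F
6	c.300G>T	VUS	54	Luminal B	No	No	1	0	Prostate, pancreatic, and glioblastoma	F
7	c.1175C>T	VUS	38	Luminal B	No	No	0	2	Gastric and bladder	F
8	c.1412C>T	VUS	39	Luminal B	No	No	1	1	Prostate and lung	F
9	c.503C>T	VUS	57	Luminal-Her2+	No	No	2	1	None	M
10	c.1420C>T	VUS	69	Luminal A	No	No	0	2	Pancreatic and prostate	F
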