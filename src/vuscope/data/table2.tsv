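variant_id	cdna	SIFT_verdict	SIFT_score	PolyPhen2_verdict	PolyPhen2_score	LRT_verdict	LRT_score	MutationTaster_verdict	MutationTaster_score	MutationAssessor_verdict	MutationAssessor_score	PROVEAN_verdict	PROVEAN_score	MetaSVM_verdict	MetaSVM_score	M-CAP_verdict	M-CAP_score	Revel_verdict	Revel_score	MutPred_verdict	MutPred_score	MVP_verdict	MVP_score	DEOGEN2_verdict	DEOGEN2_score	ClinPred_verdict	ClinPred_score	LIST-S2_verdict	LIST-S2_score	CADD_verdict	CADD_score
Q100H	c.300G>T	B	0.75	B	0.6	B	0.3	P	0.81	P	0.54	B	0.56	P	0.84	P	0.59	P	0.71	B	0.52	P	0.93	B	0.53	P	0.38	P	0.71	B	0.6
T168I	c.503C>T	P	0.78	P	0.92	P	0.84	P	0.81	P	0.9	P	0.86	P	0.98	P	0.89	P	0.99	P	0.87	P	0.98	P	0.94	P	0.85	P	0.74	P	0.71
H282D	c.844C>G	P	0.78	P	0.75	P	0.84	P	0.81	P	0.85	P	0.98	P	0.87	P	0.75	P	0.96	P	0.96	P	0.98	B	0.78	P	0.95	P	0.73	P	0.85
H345Y	c.1033C>T	P	0.91	P	0.97	P	0.84	P	0.81	P	0.86	P	0.87	P	0.91	P	0.83	P	0.98	P	0.99	P	0.97	B	0.74	P	0.89	P	0.98	P	0.84
A392V	c.1175C>T	P	0.91	P	0.78	P	0.84	P	0.81	P	0.95	P	0.72	P	0.93	P	0.88	P	0.95	NA		B	0.72	P	0.82	P	0.75	P	0.96	P	0.83
P471L	c.1412C>T	P	0.78	P	0.84	P	0.84	P	0.81	P	0.9	P	0.97	P	0.9	P	0.78	P	0.82	P	0.89	B	0.73	B	0.75	P	0.88	P	0.91	P	0.83
R474C	c.1420C>T	P	0.91	P	0.97	P	0.84	P	0.81	P	1	P	0.95	P	0.96	P	0.82	P	0.97	P	1	P	0.95	P	0.83	P	0.98	P	0.94	P	0.8
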