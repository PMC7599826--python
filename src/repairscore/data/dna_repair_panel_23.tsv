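pathway	probe_set	gene_symbol	adjusted_p	hazard_ratio	prognosis
BER	210027_s_at	APEX1	0.02	1.6	Bad
BER	209731_at	NTHL1	0.0016	1.9	Bad
BER	202330_s_at	UNG	0.0095	2	Bad
BER	203655_at	XRCC1	0.022	1.6	Bad
FANC	209902_at	ATR	0.0048	1.8	Bad
FANC	214727_at	BRCA2	0.0049	0.58	Good
FANC	203719_at	ERCC1	0.0037	1.9	Bad
FANC	203678_at	FAN1	0.0028	1.8	Bad
FANC	221206_at	PMS2 /// PMS2CL	0.024	1.8	Bad
FANC	219317_at	POLI	0.0016	1.9	Bad
HRR	214727_at	BRCA2	0.0049	0.58	Good
HRR	205395_s_at	MRE11A	0.015	1.8	Bad
HRR	205647_at	RAD52	0.044	1.9	Bad
HRR	206092_x_at	RTEL1	0.00047	2.5	Bad
HRR	212275_s_at	SRCAP	0.014	0.6	Good
HRR	207598_x_at	XRCC2	0.007	1.7	Bad
MMR	205887_x_at	MSH3	0.000043	2.8	Bad
MMR	221206_at	PMS2 /// PMS2CL	0.024	1.8	Bad
MMR	1053_at	RFC2	0.023	1.6	Bad
NER	201405_s_at	COPS6	0.011	1.7	Bad
NER	213579_s_at	EP300	0.019	0.59	Good
NER	203719_at	ERCC1	0.0037	1.9	Bad
NER	205162_at	ERCC8	0.04	1.5	Bad
NER	223758_s_at	GTF2H2	0.033	1.5	Bad
NER	201046_s_at	RAD23A	0.0067	0.53	Good
NER	205672_at	XPA	0.0035	1.8	Bad
NER	203655_at	XRCC1	0.022	1.6	Bad
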