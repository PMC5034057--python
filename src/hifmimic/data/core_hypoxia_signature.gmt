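core_hypoxia_signature	12-gene core hypoxic transcriptional signature	ADM	AK3L1	BNIP3	CA9	CCNG	ENO1	HK2	LDHA	PFKFB3	PGK1	SLC2A1	VEGFA
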