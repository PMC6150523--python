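id	generation	mother_id	father_id	coi	nuc_mat	nuc_pat	m_mat	m_pat	m_status	infected	weight_g
EfMp_0	0			f	F	F	M	m	Mp		
EfMp_1_1	1	EfMp_0	EfMp_0	f	F	F			Mp		
EfMp_1_2	1	EfMp_0	EfMp_0	f	F	F			Mp		
EfMp_1_3	1	EfMp_0	EfMp_0	f	F	F			Mp		
EfMp_1_4	1	EfMp_0	EfMp_0	f	F	F			Mp		
EfMp_1_5	1	EfMp_0	EfMp_0	f	F	F			Mp		
EfMp_1_6	1	EfMp_0	EfMp_0	f	F	F			Mn		
EfMp_1_7	1	EfMp_0	EfMp_0	f	F	F			Mn		
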