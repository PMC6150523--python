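id	generation	mother_id	father_id	coi	nuc_mat	nuc_pat	m_mat	m_pat	m_status	infected	weight_g
aAA_41	1			a	A	A			Mp		
aAA_45	1			a	A	A			Mp		
aAA_s03	1			a	A	A			Mp		
aAA_s04	1			a	A	A			Mp		
aAA_s05	1			a	A	A			Mp		
aAA_s06	1			a	A	A			Mp		
aAA_s07	1			a	A	A			Mp		
aAA_s08	1			a	A	A			Mp		
aAA_s09	1			a	A	A			Mp		
aAA_s10	1			a	A	A			Mp		
aAF_101	1			a	A	F			Mp		
aAF_s02	1			a	A	F			Mp		
aAF_s03	1			a	A	F			Mp		
aAF_s04	1			a	A	F			Mp		
aAF_s05	1			a	A	F			Mp		
aAF_s06	1			a	A	F			Mp		
aAF_s07	1			a	A	F			Mp		
aAF_s08	1			a	A	F			Mp		
aAF_s09	1			a	A	F			Mp		
aAF_s10	1			a	A	F			Mp		
aAF_s11	1			a	A	F			Mp		
aAF_s12	1			a	A	F			Mp		
aAF_s13	1			a	A	F			Mp		
aAF_s14	1			a	A	F			Mp		
aAF_s15	1			a	A	F			Mp		
aAF_s16	1			a	A	F			Mp		
aAF_s17	1			a	A	F			Mp		
aAF_s18	1			a	A	F			Mp		
aAF_s19	1			a	A	F			Mp		
fFF_42	1			f	F	F			Mn		
fFF_61	1			f	F	F			Mn		
fFF_112	1			f	F	F			Mn		
fFF_s04	1			f	F	F			Mn		
fFF_s05	1			f	F	F			Mn		
fFF_s06	1			f	F	F			Mn		
fFF_s07	1			f	F	F			Mn		
fFF_s08	1			f	F	F			Mn		
fFF_s09	1			f	F	F			Mn		
fFF_s10	1			f	F	F			Mn		
fFF_s11	1			f	F	F			Mn		
fFF_s12	1			f	F	F			Mn		
fFF_158/190	1			f	F	F			Mp		
fFA_143/159	1			f	F	A			Mp		
fFA_s2	1			f	F	A			Mp		
fFA_s3	1			f	F	A			Mp		
fFA_149/194	1			f	F	A			Mn		
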