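parameter	gene	weight
G_Na	SCN5A	1
G_CaL	CACNA1S	1
G_CaL	CACNA1D	1
G_CaL	CACNA1B	1
G_CaL	CACNA1I	1
G_CaL	CACNA1G	1
G_CaL	CACNA1H	1
G_CaL	CACNA1A	1
G_CaL	CACNA1E	1
G_CaL	CACNA1F	1
G_CaL	CACNA1C	1
G_CaL	CACNA2D1	1
G_RyR	RYR2	1
G_to	KCND2	1
G_to	KCND3	1
G_to	KCNA4	1
G_to	KCNA7	1
G_Ks	KCNQ1	1
G_Ks	KCNE1	1
G_Kr	KCNH2	1
G_K1	KCNJ2	1
G_K1	KCNJ12	1
P_NaK	ATP1A1	1
I_up	ATP2A2	1
G_pCa	ATP2B4	1
G_f	HCN2	1
G_f	HCN4	1
K_NaCa	SLC8A1	1
Trop_Conc	TNNC1	1
Myosin_scale	MYH6	1
Myosin_scale	MYH7	1
Actin_scale	ACTC1	1
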