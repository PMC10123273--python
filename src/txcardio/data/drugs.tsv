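drug_id	drug_name	final_concentration	solvent
AFA	Afatinib	50 nM	DMSO
AXI	Axitinib	200 nM	DMSO
BEV	Bevacizumab	3 uM	Water
BOS	Bosutinib	100 nM	DMSO
CAB	Cabozantinib	2 uM	DMSO
CER	Ceritinib	1 uM	DMSO
CRI	Crizotinib	0.25 uM	DMSO
CTX	Cetuximab	1 uM	Water
DAB	Dabrafenib	2.5 uM	DMSO
DAS	Dasatinib	0.1 uM	DMSO
ERL	Erlotinib	3 uM	DMSO
GEF	Gefitinib	1 uM	DMSO
IMA	Imatinib	5 uM	Water
LAP	Lapatinib	2 uM	DMSO
NIL	Nilotinib	3 uM	DMSO
PAZ	Pazopanib	10 uM	DMSO
PON	Ponatinib	100 nM	DMSO
REG	Regorafenib	1 uM	DMSO
RTX	Rituximab	3 uM	Water
SOR	Sorafenib	1 uM	DMSO
SUN	Sunitinib	1 uM	DMSO
TOF	Tofacitinib	1 uM	DMSO
TRA	Trametinib	100 nM	DMSO
TRS	Trastuzumab	3 uM	Water
VAN	Vandetanib	333 nM	DMSO
VEM	Vemurafenib	2 uM	DMSO
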