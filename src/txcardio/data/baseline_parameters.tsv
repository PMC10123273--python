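name	value	unit	note
G_Na	3671.2302	S/F	fast Na+ conductance (scalable; SCN5A)
G_CaL	8.635702e-5	m^3/(F*s)	L-type Ca2+ permeability (scalable; CACNA* genes)
G_RyR	1.0	dimensionless	SR release scale on the ten Tusscher-style release flux (scalable; RYR2)
G_to	29.9038	S/F	transient outward K+ conductance (scalable)
G_Ks	2.041	S/F	slow delayed rectifier conductance (scalable)
G_Kr	29.8667	S/F	rapid delayed rectifier conductance (scalable; KCNH2); carries sqrt(Ko/5.4)
G_K1	28.1492	S/F	inward rectifier conductance (scalable); carries sqrt(Ko/5.4)
P_NaK	1.841424	A/F	Na+/K+ pump maximum (scalable; ATP1A1)
I_up	0.56064	mM/s	SERCA maximal uptake rate Vmax (scalable; ATP2A2)
G_pCa	0.4125	A/F	sarcolemmal Ca2+ pump maximum (scalable; ATP2B4)
G_f	30.10312	S/F	funny current conductance (scalable; HCN2/HCN4)
K_NaCa	4900.0	A/F	Na+/Ca2+ exchanger maximum (scalable; SLC8A1)
Trop_Conc	0.07	mM	total troponin-C regulatory site concentration (scalable; TNNC1)
Myosin_scale	1.0	dimensionless	multiplier on maximal crossbridge force (scalable; MYH6/MYH7)
Actin_scale	1.0	dimensionless	multiplier on thin-filament availability (scalable; ACTC1)
Ko	5.4	mM	extracellular K+
Nao	151.0	mM	extracellular Na+
Cao	1.8	mM	extracellular Ca2+
Ki	150.0	mM	intracellular K+ (fixed)
Cm	9.87109e-11	F	membrane capacitance
Vc	8800.0	um^3	cytosolic volume
V_SR	583.73	um^3	SR volume
g_b_Na	0.9	S/F	background Na+ conductance
g_b_Ca	0.69264	S/F	background Ca2+ conductance
KPCa	0.0005	mM	sarcolemmal Ca2+ pump half-saturation
Km_K	1.0	mM	NaK pump Ko half-saturation
Km_Na	40.0	mM	NaK pump Nai half-saturation
KmCa	1.38	mM	NCX Ca2+ half-saturation
KmNai	87.5	mM	NCX Nai half-saturation
Ksat	0.1	dimensionless	NCX saturation factor
gamma_NCX	0.35	dimensionless	NCX voltage-dependence partition
alpha_NCX	2.8571432	dimensionless	NCX outward/inward asymmetry factor
Kup	0.00025	mM	SERCA half-saturation
V_leak	4.4444e-4	1/s	SR leak rate
a_rel	16.464	mM/s	CaSR-dependent release component
b_rel	0.25	mM	release half-saturation (CaSR)
c_rel	8.232	mM/s	constant release component
rel_gain	1.0	dimensionless	overall release gain (calibrated once to iPSC-CM CaT amplitude)
tau_g	0.002	s	release inactivation gate time constant
g_thresh	0.00015	mM	release inactivation Ca2+ threshold (scaled to iPSC-CM systolic Ca2+ range)
Buf_C	0.25	mM	cytosolic Ca2+ buffer concentration
Kbuf_C	0.001	mM	cytosolic buffer dissociation constant
Buf_SR	10.0	mM	SR Ca2+ buffer concentration
Kbuf_SR	0.3	mM	SR buffer dissociation constant
PkNa	0.03	dimensionless	IKs Na+ permeability ratio
E_f	-0.017	V	funny-current reversal potential
k_trpn_on	40.0	1/(uM*s)	troponin Ca2+ on-rate
ca50_trpn	0.12	uM	troponin Ca2+ half-activation; reduced from the adult ~0.6 uM to compensate for low iPSC-CM systolic Ca2+ (calibrated once to 5-10% baseline shortening)
n_xb	4.0	dimensionless	activation cooperativity (Hill)
f_xb	25.0	1/s	crossbridge attachment rate at full activation
g_xb	20.0	1/s	crossbridge detachment rate
sigma_act	2.0	norm/um-equivalent	maximal active force scale (calibrated to 5-10% baseline shortening)
k_passive	1.0	norm/um	passive restoring stiffness
eta_SL	0.03	norm*s/um	sarcomere viscous coefficient
SL_rest	1.9	um	resting sarcomere length
trop_ref	0.07	mM	reference troponin concentration (activation normalization)
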