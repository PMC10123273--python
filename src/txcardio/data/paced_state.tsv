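name	value
V	-0.07292901947960662
Nai	11.539658234175052
Cai	2.8249334687690516e-05
CaSR	0.09817383305055082
m	0.11144839220722637
h	0.7359052523828171
j	0.2075005715505315
d	0.00010959294262235677
f1	0.9838411263389701
f2	0.9999761554466202
fCa	0.9983283773199406
Xr1	0.010832506774542568
Xr2	0.4252275832271004
Xs	0.03525895560342905
Xf	0.08690570124501437
q	0.8228599029183582
r	0.006185513439137991
g_rel	0.9999550736413341
TRPN	0.216111888260933
XB	0.003221362427949152
SL	1.8929268761504014
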