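# Eyring activation parameters for association of scFv 11K2 variants (published values)
# dH_act in kcal/mol; mTdS_act = -T*dS_act at 298.15 K in kcal/mol
variant	dH_act	mTdS_act
WT	11.4	-0.8
L-N31R	3.4	6.8
L-S53D	4.2	6.4
L-S53E	4.5	6.4
L-T56D	3.8	6.3
L-T56E	0.7	9.9
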