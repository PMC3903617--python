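# Equilibrium van't Hoff parameters of scFv 11K2 variants (published values)
# dH in kcal/mol; mTdS = -T*dS at 298.15 K in kcal/mol
variant	dH	mTdS
WT	-7.3	-5.0
L-N31R	-25.6	12.3
L-S53D	-13.3	0.6
L-S53E	-15.1	2.4
L-T56D	-11.7	-1.1
L-T56E	-14.5	1.9
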