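# Kinetic parameters of scFv 11K2 binding to MCP-1 at 25 degC (published values)
# kon in M^-1 s^-1, koff in s^-1, KD_printed in nM (as printed, 2 s.f.)
variant	chain	T_K	kon	koff	KD_printed_nM
WT	-	298.15	14e4	1.0e-4	0.80
H-L27R	H	298.15	14e4	3.3e-4	2.4
H-L27K	H	298.15	11e4	3.9e-4	3.5
H-N28D	H	298.15	1.6e4	1.6e-4	1.0
H-N28Q	H	298.15	22e4	19e-4	8.5
H-D31E	H	298.15	3.0e4	1.5e-4	5.0
L-Y30K	L	298.15	13e4	3.1e-4	2.5
L-N31R	L	298.15	13e4	0.22e-4	0.17
L-N31K	L	298.15	34e4	980e-4	290
L-S53D	L	298.15	9.0e4	0.55e-4	0.61
L-S53E	L	298.15	7.3e4	0.14e-4	0.19
L-T56D	L	298.15	22e4	0.86e-4	0.39
L-T56E	L	298.15	10e4	0.26e-4	0.25
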