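# affimut coarse backbone-independent rotamer library v1
# chi angles in degrees; prob column sums to 1 per residue type
# columns: residue chi1 chi2 chi3 chi4 prob
SER	-65	.	.	.	0.48
SER	180	.	.	.	0.29
SER	62	.	.	.	0.23
CYS	-65	.	.	.	0.55
CYS	180	.	.	.	0.26
CYS	62	.	.	.	0.19
THR	-60	.	.	.	0.49
THR	62	.	.	.	0.43
THR	180	.	.	.	0.08
VAL	175	.	.	.	0.73
VAL	-60	.	.	.	0.20
VAL	62	.	.	.	0.07
LEU	-65	175	.	.	0.62
LEU	180	65	.	.	0.30
LEU	62	180	.	.	0.08
ILE	-65	170	.	.	0.60
ILE	-60	-60	.	.	0.15
ILE	62	170	.	.	0.15
ILE	180	165	.	.	0.10
MET	-65	180	-70	.	0.35
MET	-65	180	180	.	0.25
MET	180	180	180	.	0.25
MET	-65	-65	-70	.	0.15
PHE	-65	90	.	.	0.50
PHE	180	80	.	.	0.35
PHE	62	90	.	.	0.15
TYR	-65	90	.	.	0.50
TYR	180	80	.	.	0.35
TYR	62	90	.	.	0.15
TRP	-65	95	.	.	0.40
TRP	180	-105	.	.	0.35
TRP	62	-90	.	.	0.25
ASP	-70	-15	.	.	0.55
ASP	180	15	.	.	0.30
ASP	62	15	.	.	0.15
ASN	-65	-20	.	.	0.45
ASN	180	30	.	.	0.35
ASN	62	-20	.	.	0.20
GLU	-65	180	-10	.	0.40
GLU	180	180	15	.	0.35
GLU	-65	-65	-10	.	0.25
GLN	-65	180	-25	.	0.40
GLN	180	180	20	.	0.35
GLN	-65	-65	-40	.	0.25
HIS	-65	-70	.	.	0.45
HIS	180	60	.	.	0.35
HIS	62	-75	.	.	0.20
LYS	-65	180	180	180	0.40
LYS	180	180	180	180	0.35
LYS	-65	-65	180	180	0.25
ARG	-65	180	180	180	0.35
ARG	180	180	180	180	0.30
ARG	-65	180	-65	180	0.20
ARG	180	180	-85	180	0.15
PRO	-27	36	.	.	0.60
PRO	28	-35	.	.	0.40
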