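# affimut united-atom nonbonded parameter table v1
# hydrogens omitted; their charges are folded into bonded heavy atoms
# dispersion well depths are half of AMBER-type values: net dispersion in
# water is strongly screened, and the score is designed so that charge
# complementarity dominates interface energetics
# columns: residue atom charge(e) rmin2(A) eps(kcal/mol) radius(A)
ALA	N	-0.500	1.824	0.0850	1.55
ALA	CA	+0.500	1.908	0.0545	1.70
ALA	C	+0.550	1.908	0.0545	1.70
ALA	O	-0.550	1.661	0.1050	1.52
ALA	OXT	+0.000	1.661	0.1050	1.52
ALA	CB	+0.000	1.908	0.0545	1.70
ARG	N	-0.500	1.824	0.0850	1.55
ARG	CA	+0.500	1.908	0.0545	1.70
ARG	C	+0.550	1.908	0.0545	1.70
ARG	O	-0.550	1.661	0.1050	1.52
ARG	OXT	+0.000	1.661	0.1050	1.52
ARG	CB	+0.000	1.908	0.0545	1.70
ARG	CG	+0.000	1.908	0.0545	1.70
ARG	CD	+0.100	1.908	0.0545	1.70
ARG	NE	-0.400	1.824	0.0850	1.55
ARG	CZ	+0.600	1.908	0.0545	1.70
ARG	NH1	+0.350	1.824	0.0850	1.55
ARG	NH2	+0.350	1.824	0.0850	1.55
ASN	N	-0.500	1.824	0.0850	1.55
ASN	CA	+0.500	1.908	0.0545	1.70
ASN	C	+0.550	1.908	0.0545	1.70
ASN	O	-0.550	1.661	0.1050	1.52
ASN	OXT	+0.000	1.661	0.1050	1.52
ASN	CB	+0.000	1.908	0.0545	1.70
ASN	CG	+0.550	1.908	0.0545	1.70
ASN	OD1	-0.550	1.661	0.1050	1.52
ASN	ND2	+0.000	1.824	0.0850	1.55
ASP	N	-0.500	1.824	0.0850	1.55
ASP	CA	+0.500	1.908	0.0545	1.70
ASP	C	+0.550	1.908	0.0545	1.70
ASP	O	-0.550	1.661	0.1050	1.52
ASP	OXT	+0.000	1.661	0.1050	1.52
ASP	CB	+0.000	1.908	0.0545	1.70
ASP	CG	+0.300	1.908	0.0545	1.70
ASP	OD1	-0.650	1.661	0.1050	1.52
ASP	OD2	-0.650	1.661	0.1050	1.52
CYS	N	-0.500	1.824	0.0850	1.55
CYS	CA	+0.500	1.908	0.0545	1.70
CYS	C	+0.550	1.908	0.0545	1.70
CYS	O	-0.550	1.661	0.1050	1.52
CYS	OXT	+0.000	1.661	0.1050	1.52
CYS	CB	+0.100	1.908	0.0545	1.70
CYS	SG	-0.100	2.000	0.1250	1.80
GLN	N	-0.500	1.824	0.0850	1.55
GLN	CA	+0.500	1.908	0.0545	1.70
GLN	C	+0.550	1.908	0.0545	1.70
GLN	O	-0.550	1.661	0.1050	1.52
GLN	OXT	+0.000	1.661	0.1050	1.52
GLN	CB	+0.000	1.908	0.0545	1.70
GLN	CG	+0.000	1.908	0.0545	1.70
GLN	CD	+0.550	1.908	0.0545	1.70
GLN	OE1	-0.550	1.661	0.1050	1.52
GLN	NE2	+0.000	1.824	0.0850	1.55
GLU	N	-0.500	1.824	0.0850	1.55
GLU	CA	+0.500	1.908	0.0545	1.70
GLU	C	+0.550	1.908	0.0545	1.70
GLU	O	-0.550	1.661	0.1050	1.52
GLU	OXT	+0.000	1.661	0.1050	1.52
GLU	CB	+0.000	1.908	0.0545	1.70
GLU	CG	+0.000	1.908	0.0545	1.70
GLU	CD	+0.300	1.908	0.0545	1.70
GLU	OE1	-0.650	1.661	0.1050	1.52
GLU	OE2	-0.650	1.661	0.1050	1.52
GLY	N	-0.500	1.824	0.0850	1.55
GLY	CA	+0.500	1.908	0.0545	1.70
GLY	C	+0.550	1.908	0.0545	1.70
GLY	O	-0.550	1.661	0.1050	1.52
GLY	OXT	+0.000	1.661	0.1050	1.52
HIS	N	-0.500	1.824	0.0850	1.55
HIS	CA	+0.500	1.908	0.0545	1.70
HIS	C	+0.550	1.908	0.0545	1.70
HIS	O	-0.550	1.661	0.1050	1.52
HIS	OXT	+0.000	1.661	0.1050	1.52
HIS	CB	+0.000	1.908	0.0545	1.70
HIS	CG	+0.000	1.908	0.0545	1.70
HIS	ND1	-0.200	1.824	0.0850	1.55
HIS	CD2	+0.000	1.908	0.0545	1.70
HIS	CE1	+0.200	1.908	0.0545	1.70
HIS	NE2	+0.000	1.824	0.0850	1.55
ILE	N	-0.500	1.824	0.0850	1.55
ILE	CA	+0.500	1.908	0.0545	1.70
ILE	C	+0.550	1.908	0.0545	1.70
ILE	O	-0.550	1.661	0.1050	1.52
ILE	OXT	+0.000	1.661	0.1050	1.52
ILE	CB	+0.000	1.908	0.0545	1.70
ILE	CG1	+0.000	1.908	0.0545	1.70
ILE	CG2	+0.000	1.908	0.0545	1.70
ILE	CD1	+0.000	1.908	0.0545	1.70
LEU	N	-0.500	1.824	0.0850	1.55
LEU	CA	+0.500	1.908	0.0545	1.70
LEU	C	+0.550	1.908	0.0545	1.70
LEU	O	-0.550	1.661	0.1050	1.52
LEU	OXT	+0.000	1.661	0.1050	1.52
LEU	CB	+0.000	1.908	0.0545	1.70
LEU	CG	+0.000	1.908	0.0545	1.70
LEU	CD1	+0.000	1.908	0.0545	1.70
LEU	CD2	+0.000	1.908	0.0545	1.70
LYS	N	-0.500	1.824	0.0850	1.55
LYS	CA	+0.500	1.908	0.0545	1.70
LYS	C	+0.550	1.908	0.0545	1.70
LYS	O	-0.550	1.661	0.1050	1.52
LYS	OXT	+0.000	1.661	0.1050	1.52
LYS	CB	+0.000	1.908	0.0545	1.70
LYS	CG	+0.000	1.908	0.0545	1.70
LYS	CD	+0.000	1.908	0.0545	1.70
LYS	CE	+0.250	1.908	0.0545	1.70
LYS	NZ	+0.750	1.824	0.0850	1.55
MET	N	-0.500	1.824	0.0850	1.55
MET	CA	+0.500	1.908	0.0545	1.70
MET	C	+0.550	1.908	0.0545	1.70
MET	O	-0.550	1.661	0.1050	1.52
MET	OXT	+0.000	1.661	0.1050	1.52
MET	CB	+0.000	1.908	0.0545	1.70
MET	CG	+0.050	1.908	0.0545	1.70
MET	SD	-0.100	2.000	0.1250	1.80
MET	CE	+0.050	1.908	0.0545	1.70
PHE	N	-0.500	1.824	0.0850	1.55
PHE	CA	+0.500	1.908	0.0545	1.70
PHE	C	+0.550	1.908	0.0545	1.70
PHE	O	-0.550	1.661	0.1050	1.52
PHE	OXT	+0.000	1.661	0.1050	1.52
PHE	CB	+0.000	1.908	0.0545	1.70
PHE	CG	+0.000	1.908	0.0545	1.70
PHE	CD1	+0.000	1.908	0.0545	1.70
PHE	CD2	+0.000	1.908	0.0545	1.70
PHE	CE1	+0.000	1.908	0.0545	1.70
PHE	CE2	+0.000	1.908	0.0545	1.70
PHE	CZ	+0.000	1.908	0.0545	1.70
PRO	N	-0.500	1.824	0.0850	1.55
PRO	CA	+0.500	1.908	0.0545	1.70
PRO	C	+0.550	1.908	0.0545	1.70
PRO	O	-0.550	1.661	0.1050	1.52
PRO	OXT	+0.000	1.661	0.1050	1.52
PRO	CB	+0.000	1.908	0.0545	1.70
PRO	CG	+0.000	1.908	0.0545	1.70
PRO	CD	+0.000	1.908	0.0545	1.70
SER	N	-0.500	1.824	0.0850	1.55
SER	CA	+0.500	1.908	0.0545	1.70
SER	C	+0.550	1.908	0.0545	1.70
SER	O	-0.550	1.661	0.1050	1.52
SER	OXT	+0.000	1.661	0.1050	1.52
SER	CB	+0.250	1.908	0.0545	1.70
SER	OG	-0.250	1.661	0.1050	1.52
THR	N	-0.500	1.824	0.0850	1.55
THR	CA	+0.500	1.908	0.0545	1.70
THR	C	+0.550	1.908	0.0545	1.70
THR	O	-0.550	1.661	0.1050	1.52
THR	OXT	+0.000	1.661	0.1050	1.52
THR	CB	+0.250	1.908	0.0545	1.70
THR	OG1	-0.250	1.661	0.1050	1.52
THR	CG2	+0.000	1.908	0.0545	1.70
TRP	N	-0.500	1.824	0.0850	1.55
TRP	CA	+0.500	1.908	0.0545	1.70
TRP	C	+0.550	1.908	0.0545	1.70
TRP	O	-0.550	1.661	0.1050	1.52
TRP	OXT	+0.000	1.661	0.1050	1.52
TRP	CB	+0.000	1.908	0.0545	1.70
TRP	CG	+0.000	1.908	0.0545	1.70
TRP	CD1	+0.150	1.908	0.0545	1.70
TRP	CD2	+0.000	1.908	0.0545	1.70
TRP	NE1	-0.300	1.824	0.0850	1.55
TRP	CE2	+0.150	1.908	0.0545	1.70
TRP	CE3	+0.000	1.908	0.0545	1.70
TRP	CZ2	+0.000	1.908	0.0545	1.70
TRP	CZ3	+0.000	1.908	0.0545	1.70
TRP	CH2	+0.000	1.908	0.0545	1.70
TYR	N	-0.500	1.824	0.0850	1.55
TYR	CA	+0.500	1.908	0.0545	1.70
TYR	C	+0.550	1.908	0.0545	1.70
TYR	O	-0.550	1.661	0.1050	1.52
TYR	OXT	+0.000	1.661	0.1050	1.52
TYR	CB	+0.000	1.908	0.0545	1.70
TYR	CG	+0.000	1.908	0.0545	1.70
TYR	CD1	+0.000	1.908	0.0545	1.70
TYR	CD2	+0.000	1.908	0.0545	1.70
TYR	CE1	+0.000	1.908	0.0545	1.70
TYR	CE2	+0.000	1.908	0.0545	1.70
TYR	CZ	+0.250	1.908	0.0545	1.70
TYR	OH	-0.250	1.661	0.1050	1.52
VAL	N	-0.500	1.824	0.0850	1.55
VAL	CA	+0.500	1.908	0.0545	1.70
VAL	C	+0.550	1.908	0.0545	1.70
VAL	O	-0.550	1.661	0.1050	1.52
VAL	OXT	+0.000	1.661	0.1050	1.52
VAL	CB	+0.000	1.908	0.0545	1.70
VAL	CG1	+0.000	1.908	0.0545	1.70
VAL	CG2	+0.000	1.908	0.0545	1.70
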