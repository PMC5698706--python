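# Simplified polar-hydrogen charge/radius set for continuum electrostatics.
# Explicit polar hydrogens only; per-residue charges sum to the formal charge.
# '*' rows are terminal backbone patches overriding the default backbone atoms.
res_name	atom_name	variant	charge	radius
GLY	N	default	-0.4000	1.50
GLY	H	default	0.2500	1.00
GLY	CA	default	0.1000	1.70
GLY	C	default	0.5500	1.70
GLY	O	default	-0.5000	1.40
ALA	N	default	-0.4000	1.50
ALA	H	default	0.2500	1.00
ALA	CA	default	0.1000	1.70
ALA	C	default	0.5500	1.70
ALA	O	default	-0.5000	1.40
ALA	CB	default	0.0000	1.70
VAL	N	default	-0.4000	1.50
VAL	H	default	0.2500	1.00
VAL	CA	default	0.1000	1.70
VAL	C	default	0.5500	1.70
VAL	O	default	-0.5000	1.40
VAL	CB	default	0.0000	1.70
VAL	CG1	default	0.0000	1.70
VAL	CG2	default	0.0000	1.70
LEU	N	default	-0.4000	1.50
LEU	H	default	0.2500	1.00
LEU	CA	default	0.1000	1.70
LEU	C	default	0.5500	1.70
LEU	O	default	-0.5000	1.40
LEU	CB	default	0.0000	1.70
LEU	CG	default	0.0000	1.70
LEU	CD1	default	0.0000	1.70
LEU	CD2	default	0.0000	1.70
ILE	N	default	-0.4000	1.50
ILE	H	default	0.2500	1.00
ILE	CA	default	0.1000	1.70
ILE	C	default	0.5500	1.70
ILE	O	default	-0.5000	1.40
ILE	CB	default	0.0000	1.70
ILE	CG1	default	0.0000	1.70
ILE	CG2	default	0.0000	1.70
ILE	CD1	default	0.0000	1.70
MET	N	default	-0.4000	1.50
MET	H	default	0.2500	1.00
MET	CA	default	0.1000	1.70
MET	C	default	0.5500	1.70
MET	O	default	-0.5000	1.40
MET	CB	default	0.0000	1.70
MET	CG	default	0.0600	1.70
MET	SD	default	-0.1200	1.85
MET	CE	default	0.0600	1.70
PHE	N	default	-0.4000	1.50
PHE	H	default	0.2500	1.00
PHE	CA	default	0.1000	1.70
PHE	C	default	0.5500	1.70
PHE	O	default	-0.5000	1.40
PHE	CB	default	0.0000	1.70
PHE	CG	default	0.0000	1.70
PHE	CD1	default	0.0000	1.70
PHE	CD2	default	0.0000	1.70
PHE	CE1	default	0.0000	1.70
PHE	CE2	default	0.0000	1.70
PHE	CZ	default	0.0000	1.70
TYR	N	default	-0.4000	1.50
TYR	H	default	0.2500	1.00
TYR	CA	default	0.1000	1.70
TYR	C	default	0.5500	1.70
TYR	O	default	-0.5000	1.40
TYR	CB	default	0.0000	1.70
TYR	CG	default	0.0000	1.70
TYR	CD1	default	0.0000	1.70
TYR	CD2	default	0.0000	1.70
TYR	CE1	default	0.0000	1.70
TYR	CE2	default	0.0000	1.70
TYR	CZ	default	0.2500	1.70
TYR	OH	default	-0.6500	1.40
TYR	HH	default	0.4000	1.00
TRP	N	default	-0.4000	1.50
TRP	H	default	0.2500	1.00
TRP	CA	default	0.1000	1.70
TRP	C	default	0.5500	1.70
TRP	O	default	-0.5000	1.40
TRP	CB	default	0.0000	1.70
TRP	CG	default	0.0000	1.70
TRP	CD1	default	0.0000	1.70
TRP	CD2	default	0.0000	1.70
TRP	NE1	default	-0.3000	1.50
TRP	HE1	default	0.3000	1.00
TRP	CE2	default	0.0000	1.70
TRP	CE3	default	0.0000	1.70
TRP	CZ2	default	0.0000	1.70
TRP	CZ3	default	0.0000	1.70
TRP	CH2	default	0.0000	1.70
SER	N	default	-0.4000	1.50
SER	H	default	0.2500	1.00
SER	CA	default	0.1000	1.70
SER	C	default	0.5500	1.70
SER	O	default	-0.5000	1.40
SER	CB	default	0.2500	1.70
SER	OG	default	-0.6500	1.40
SER	HG	default	0.4000	1.00
THR	N	default	-0.4000	1.50
THR	H	default	0.2500	1.00
THR	CA	default	0.1000	1.70
THR	C	default	0.5500	1.70
THR	O	default	-0.5000	1.40
THR	CB	default	0.2500	1.70
THR	OG1	default	-0.6500	1.40
THR	HG1	default	0.4000	1.00
THR	CG2	default	0.0000	1.70
CYS	N	default	-0.4000	1.50
CYS	H	default	0.2500	1.00
CYS	CA	default	0.1000	1.70
CYS	C	default	0.5500	1.70
CYS	O	default	-0.5000	1.40
CYS	CB	default	0.1000	1.70
CYS	SG	default	-0.3500	1.85
CYS	HG	default	0.2500	1.00
ASN	N	default	-0.4000	1.50
ASN	H	default	0.2500	1.00
ASN	CA	default	0.1000	1.70
ASN	C	default	0.5500	1.70
ASN	O	default	-0.5000	1.40
ASN	CB	default	0.0000	1.70
ASN	CG	default	0.5500	1.70
ASN	OD1	default	-0.5500	1.40
ASN	ND2	default	-0.6000	1.50
ASN	HD21	default	0.3000	1.00
ASN	HD22	default	0.3000	1.00
GLN	N	default	-0.4000	1.50
GLN	H	default	0.2500	1.00
GLN	CA	default	0.1000	1.70
GLN	C	default	0.5500	1.70
GLN	O	default	-0.5000	1.40
GLN	CB	default	0.0000	1.70
GLN	CG	default	0.0000	1.70
GLN	CD	default	0.5500	1.70
GLN	OE1	default	-0.5500	1.40
GLN	NE2	default	-0.6000	1.50
GLN	HE21	default	0.3000	1.00
GLN	HE22	default	0.3000	1.00
ASP	N	default	-0.4000	1.50
ASP	H	default	0.2500	1.00
ASP	CA	default	0.1000	1.70
ASP	C	default	0.5500	1.70
ASP	O	default	-0.5000	1.40
ASP	CB	default	0.0000	1.70
ASP	CG	default	0.1000	1.70
ASP	OD1	default	-0.5500	1.40
ASP	OD2	default	-0.5500	1.40
GLU	N	default	-0.4000	1.50
GLU	H	default	0.2500	1.00
GLU	CA	default	0.1000	1.70
GLU	C	default	0.5500	1.70
GLU	O	default	-0.5000	1.40
GLU	CB	default	0.0000	1.70
GLU	CG	default	0.0000	1.70
GLU	CD	default	0.1000	1.70
GLU	OE1	default	-0.5500	1.40
GLU	OE2	default	-0.5500	1.40
LYS	N	default	-0.4000	1.50
LYS	H	default	0.2500	1.00
LYS	CA	default	0.1000	1.70
LYS	C	default	0.5500	1.70
LYS	O	default	-0.5000	1.40
LYS	CB	default	0.0000	1.70
LYS	CG	default	0.0000	1.70
LYS	CD	default	0.0000	1.70
LYS	CE	default	0.2500	1.70
LYS	NZ	default	-0.3000	1.50
LYS	HZ1	default	0.3500	1.00
LYS	HZ2	default	0.3500	1.00
LYS	HZ3	default	0.3500	1.00
ARG	N	default	-0.4000	1.50
ARG	H	default	0.2500	1.00
ARG	CA	default	0.1000	1.70
ARG	C	default	0.5500	1.70
ARG	O	default	-0.5000	1.40
ARG	CB	default	0.0000	1.70
ARG	CG	default	0.0000	1.70
ARG	CD	default	0.1000	1.70
ARG	NE	default	-0.4000	1.50
ARG	HE	default	0.3000	1.00
ARG	CZ	default	0.5000	1.70
ARG	NH1	default	-0.4500	1.50
ARG	HH11	default	0.3500	1.00
ARG	HH12	default	0.3500	1.00
ARG	NH2	default	-0.4500	1.50
ARG	HH21	default	0.3500	1.00
ARG	HH22	default	0.3500	1.00
HIS	N	default	-0.4000	1.50
HIS	H	default	0.2500	1.00
HIS	CA	default	0.1000	1.70
HIS	C	default	0.5500	1.70
HIS	O	default	-0.5000	1.40
HIS	CB	default	0.0000	1.70
HIS	CG	default	0.1000	1.70
HIS	ND1	default	-0.4000	1.50
HIS	HD1	default	0.3000	1.00
HIS	CD2	default	0.1000	1.70
HIS	CE1	default	0.3000	1.70
HIS	NE2	default	-0.4000	1.50
PRO	N	default	-0.2500	1.50
PRO	CA	default	0.1000	1.70
PRO	C	default	0.5500	1.70
PRO	O	default	-0.5000	1.40
PRO	CB	default	0.0000	1.70
PRO	CG	default	0.0000	1.70
PRO	CD	default	0.1000	1.70
LYS	N	neutral	-0.4000	1.50
LYS	H	neutral	0.2500	1.00
LYS	CA	neutral	0.1000	1.70
LYS	C	neutral	0.5500	1.70
LYS	O	neutral	-0.5000	1.40
LYS	CB	neutral	0.0000	1.70
LYS	CG	neutral	0.0000	1.70
LYS	CD	neutral	0.0000	1.70
LYS	CE	neutral	0.2500	1.70
LYS	NZ	neutral	-0.9500	1.50
LYS	HZ1	neutral	0.3500	1.00
LYS	HZ2	neutral	0.3500	1.00
CYS	N	disulfide	-0.4000	1.50
CYS	H	disulfide	0.2500	1.00
CYS	CA	disulfide	0.1000	1.70
CYS	C	disulfide	0.5500	1.70
CYS	O	disulfide	-0.5000	1.40
CYS	CB	disulfide	0.0500	1.70
CYS	SG	disulfide	-0.0500	1.85
CYS	N	thiolate	-0.4000	1.50
CYS	H	thiolate	0.2500	1.00
CYS	CA	thiolate	0.1000	1.70
CYS	C	thiolate	0.5500	1.70
CYS	O	thiolate	-0.5000	1.40
CYS	CB	thiolate	0.0000	1.70
CYS	SG	thiolate	-1.0000	1.85
HIS	N	ne2	-0.4000	1.50
HIS	H	ne2	0.2500	1.00
HIS	CA	ne2	0.1000	1.70
HIS	C	ne2	0.5500	1.70
HIS	O	ne2	-0.5000	1.40
HIS	CB	ne2	0.0000	1.70
HIS	CG	ne2	0.1000	1.70
HIS	ND1	ne2	-0.4000	1.50
HIS	CD2	ne2	0.1000	1.70
HIS	CE1	ne2	0.3000	1.70
HIS	NE2	ne2	-0.4000	1.50
HIS	HE2	ne2	0.3000	1.00
HIS	N	protonated	-0.4000	1.50
HIS	H	protonated	0.2500	1.00
HIS	CA	protonated	0.1000	1.70
HIS	C	protonated	0.5500	1.70
HIS	O	protonated	-0.5000	1.40
HIS	CB	protonated	0.2500	1.70
HIS	CG	protonated	0.1000	1.70
HIS	ND1	protonated	-0.3000	1.50
HIS	HD1	protonated	0.3500	1.00
HIS	CD2	protonated	0.1000	1.70
HIS	CE1	protonated	0.4500	1.70
HIS	NE2	protonated	-0.3000	1.50
HIS	HE2	protonated	0.3500	1.00
*	N	nter	-0.3000	1.50
*	H1	nter	0.3500	1.00
*	H2	nter	0.3500	1.00
*	H3	nter	0.3500	1.00
*	CA	nter	0.2000	1.70
*	C	cter	0.3000	1.70
*	O	cter	-0.6250	1.40
*	OXT	cter	-0.6250	1.40
CU	CU	default	0.0000	1.71
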