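aa1	aa2	kappa
ALA	ALA	0.668
ALA	ARG	0.226
ALA	ASN	0.226
ALA	ASP	0.226
ALA	CYS	0.794
ALA	GLN	0.226
ALA	GLU	0.226
ALA	GLY	0.389
ALA	HIS	0.226
ALA	ILE	1.3
ALA	LEU	1.094
ALA	LYS	0.226
ALA	MET	0.685
ALA	PHE	0.855
ALA	PRO	0.289
ALA	SER	0.352
ALA	THR	0.361
ALA	TRP	0.344
ALA	TYR	0.311
ALA	VAL	1.207
ARG	ARG	0.226
ARG	ASN	0.226
ARG	ASP	0.226
ARG	CYS	0.226
ARG	GLN	0.226
ARG	GLU	0.226
ARG	GLY	0.226
ARG	HIS	0.226
ARG	ILE	0.275
ARG	LEU	0.232
ARG	LYS	0.226
ARG	MET	0.226
ARG	PHE	0.226
ARG	PRO	0.226
ARG	SER	0.226
ARG	THR	0.226
ARG	TRP	0.226
ARG	TYR	0.226
ARG	VAL	0.256
ASN	ASN	0.226
ASN	ASP	0.226
ASN	CYS	0.226
ASN	GLN	0.226
ASN	GLU	0.226
ASN	GLY	0.226
ASN	HIS	0.226
ASN	ILE	0.352
ASN	LEU	0.296
ASN	LYS	0.226
ASN	MET	0.226
ASN	PHE	0.232
ASN	PRO	0.226
ASN	SER	0.226
ASN	THR	0.226
ASN	TRP	0.226
ASN	TYR	0.226
ASN	VAL	0.327
ASP	ASP	0.226
ASP	CYS	0.226
ASP	GLN	0.226
ASP	GLU	0.226
ASP	GLY	0.226
ASP	HIS	0.226
ASP	ILE	0.352
ASP	LEU	0.296
ASP	LYS	0.226
ASP	MET	0.226
ASP	PHE	0.232
ASP	PRO	0.226
ASP	SER	0.226
ASP	THR	0.226
ASP	TRP	0.226
ASP	TYR	0.226
ASP	VAL	0.327
CYS	CYS	0.944
CYS	GLN	0.226
CYS	GLU	0.226
CYS	GLY	0.462
CYS	HIS	0.232
CYS	ILE	1.544
CYS	LEU	1.3
CYS	LYS	0.226
CYS	MET	0.814
CYS	PHE	1.016
CYS	PRO	0.344
CYS	SER	0.418
CYS	THR	0.429
CYS	TRP	0.408
CYS	TYR	0.37
CYS	VAL	1.434
GLN	GLN	0.226
GLN	GLU	0.226
GLN	GLY	0.226
GLN	HIS	0.226
GLN	ILE	0.352
GLN	LEU	0.296
GLN	LYS	0.226
GLN	MET	0.226
GLN	PHE	0.232
GLN	PRO	0.226
GLN	SER	0.226
GLN	THR	0.226
GLN	TRP	0.226
GLN	TYR	0.226
GLN	VAL	0.327
GLU	GLU	0.226
GLU	GLY	0.226
GLU	HIS	0.226
GLU	ILE	0.352
GLU	LEU	0.296
GLU	LYS	0.226
GLU	MET	0.226
GLU	PHE	0.232
GLU	PRO	0.226
GLU	SER	0.226
GLU	THR	0.226
GLU	TRP	0.226
GLU	TYR	0.226
GLU	VAL	0.327
GLY	GLY	0.226
GLY	HIS	0.226
GLY	ILE	0.756
GLY	LEU	0.636
GLY	LYS	0.226
GLY	MET	0.398
GLY	PHE	0.497
GLY	PRO	0.226
GLY	SER	0.226
GLY	THR	0.226
GLY	TRP	0.226
GLY	TYR	0.226
GLY	VAL	0.702
HIS	HIS	0.226
HIS	ILE	0.379
HIS	LEU	0.319
HIS	LYS	0.226
HIS	MET	0.226
HIS	PHE	0.249
HIS	PRO	0.226
HIS	SER	0.226
HIS	THR	0.226
HIS	TRP	0.226
HIS	TYR	0.226
HIS	VAL	0.352
ILE	ILE	2.348
ILE	LEU	2.128
ILE	LYS	0.319
ILE	MET	1.332
ILE	PHE	1.663
ILE	PRO	0.562
ILE	SER	0.685
ILE	THR	0.702
ILE	TRP	0.668
ILE	TYR	0.606
ILE	VAL	2.348
LEU	LEU	1.791
LEU	LYS	0.269
LEU	MET	1.121
LEU	PHE	1.4
LEU	PRO	0.473
LEU	SER	0.576
LEU	THR	0.591
LEU	TRP	0.562
LEU	TYR	0.51
LEU	VAL	1.976
LYS	LYS	0.226
LYS	MET	0.226
LYS	PHE	0.226
LYS	PRO	0.226
LYS	SER	0.226
LYS	THR	0.226
LYS	TRP	0.226
LYS	TYR	0.226
LYS	VAL	0.296
MET	MET	0.702
MET	PHE	0.876
MET	PRO	0.296
MET	SER	0.361
MET	THR	0.37
MET	TRP	0.352
MET	TYR	0.319
MET	VAL	1.237
PHE	PHE	1.094
PHE	PRO	0.37
PHE	SER	0.451
PHE	THR	0.462
PHE	TRP	0.44
PHE	TYR	0.398
PHE	VAL	1.544
PRO	PRO	0.226
PRO	SER	0.226
PRO	THR	0.226
PRO	TRP	0.226
PRO	TYR	0.226
PRO	VAL	0.522
SER	SER	0.226
SER	THR	0.226
SER	TRP	0.226
SER	TYR	0.226
SER	VAL	0.636
THR	THR	0.226
THR	TRP	0.226
THR	TYR	0.226
THR	VAL	0.652
TRP	TRP	0.226
TRP	TYR	0.226
TRP	VAL	0.621
TYR	TYR	0.226
TYR	VAL	0.562
VAL	VAL	2.181
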