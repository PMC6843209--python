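residue	chem_class
ALA	hydrophobic
VAL	hydrophobic
LEU	hydrophobic
ILE	hydrophobic
MET	hydrophobic
PHE	hydrophobic
TRP	hydrophobic
PRO	hydrophobic
GLY	hydrophobic
SER	polar
THR	polar
CYS	polar
TYR	polar
ASN	polar
GLN	polar
HIS	polar
ASP	charged
GLU	charged
LYS	charged
ARG	charged
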