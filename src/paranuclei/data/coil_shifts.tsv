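# Random-coil 13C chemical shifts (ppm) of the 20 standard amino acids,
# Wishart et al., J. Biomol. NMR 5, 67-81 (1995); Gly has no CB.
residue	CA	CB
ALA	52.5	19.1
ARG	56.0	30.9
ASN	53.1	38.9
ASP	54.2	41.1
CYS	58.2	28.0
GLN	55.7	29.4
GLU	56.6	29.9
GLY	45.1
HIS	55.0	29.0
ILE	61.1	38.8
LEU	55.1	42.4
LYS	56.2	33.1
MET	55.4	32.9
PHE	57.7	39.6
PRO	63.3	32.1
SER	58.3	63.8
THR	61.8	69.8
TRP	57.5	29.3
TYR	57.9	38.8
VAL	62.2	32.9
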