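# Side-chain pseudocenter templates, one row per center.
# kind: DON donor | ACC acceptor | DAC mixed donor/acceptor | ALI aliphatic | ARO aromatic/pi
# center_atoms: atoms averaged for the center position (comma separated)
# ref_atoms: reference atoms for the interaction direction v
# v_rule: away  -> v = unit(center - mean(ref_atoms))
#         ring  -> v = unit((a2-a1) x (a3-a1)) over the first three center_atoms
#         none  -> isotropic (no v); ALI only
# Backbone centers (N -> DON bisecting C-N-CA, O -> ACC along C=O) are built in code.
# Toy pseudo-residue types (T??) are used by the synthetic-fixture generator.
resname	kind	center_atoms	ref_atoms	v_rule
SER	DAC	OG	CB	away
THR	DAC	OG1	CB	away
THR	ALI	CG2	-	none
TYR	DAC	OH	CZ	away
TYR	ARO	CG,CD1,CD2,CE1,CE2,CZ	-	ring
TYR	ALI	CB	-	none
HIS	DAC	ND1	CG,CE1	away
HIS	DAC	NE2	CD2,CE1	away
HIS	ARO	CG,ND1,CD2,CE1,NE2	-	ring
LYS	DON	NZ	CE	away
LYS	ALI	CB,CG,CD	-	none
ARG	DON	NE	CD,CZ	away
ARG	DON	NH1	CZ	away
ARG	DON	NH2	CZ	away
ARG	ALI	CB,CG	-	none
ASP	ACC	OD1	CG	away
ASP	ACC	OD2	CG	away
ASP	ALI	CB	-	none
GLU	ACC	OE1	CD	away
GLU	ACC	OE2	CD	away
GLU	ALI	CB,CG	-	none
ASN	DON	ND2	CG	away
ASN	ACC	OD1	CG	away
ASN	ALI	CB	-	none
GLN	DON	NE2	CD	away
GLN	ACC	OE1	CD	away
GLN	ALI	CB,CG	-	none
TRP	DON	NE1	CD1,CE2	away
TRP	ARO	CG,CD1,NE1,CE2,CD2	-	ring
TRP	ARO	CD2,CE2,CZ2,CH2,CZ3,CE3	-	ring
TRP	ALI	CB	-	none
PHE	ARO	CG,CD1,CD2,CE1,CE2,CZ	-	ring
PHE	ALI	CB	-	none
CYS	DON	SG	CB	away
MET	ACC	SD	CG,CE	away
MET	ALI	CB,CG,CE	-	none
ALA	ALI	CB	-	none
VAL	ALI	CB,CG1,CG2	-	none
LEU	ALI	CB,CG,CD1,CD2	-	none
ILE	ALI	CB,CG1,CG2,CD1	-	none
PRO	ALI	CB,CG,CD	-	none
TDN	DON	N1	C1	away
TAC	ACC	O1	C1	away
TAR	ARO	C1,C2,C3,C4,C5,C6	-	ring
TAL	ALI	C1,C2	-	none
TCP	DON	N1	C1	away
TCN	ACC	O1	C1	away
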