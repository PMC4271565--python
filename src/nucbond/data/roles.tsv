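# nucbond hydrogen-bond role dictionary, v1.
# One row per (residue group, atom): whether the atom can donate and/or accept
# hydrogen bonds, its donor geometry class, the frame atoms used to place the
# hydrogen, and the acceptor antecedent atoms used for the H-A-AA angle.
#
# residue groups: @protein = 20 standard amino acids; @protein!PRO excludes
# proline; @nt = all 8 standard (deoxy)ribonucleotides; @ribo = A,C,G,U.
# Comma lists of residue names are also accepted.
# frame / antecedent tokens: C^- = C of the previous residue; P^+ = P of the
# next residue (used only when actually bonded).
# donor_geometry: bisector = single sp2 H on the external bisector of two
# bonded heavy atoms; amide2 = two sp2 H in the plane of (ref, parent, N);
# rotor = single sp3 H on the tetrahedral cone about the parent bond;
# rotor3 = three sp3 H on the cone (ammonium).
# terminal_only = 1: the donor role applies only at a chain terminus
# (hydroxyl O3'/O5' with no bonded phosphate).
residue	atom	donor	acceptor	rotatable	donor_geometry	frame	antecedents	terminal_only
@protein!PRO	N	1	0	0	bisector	C^-,CA	-	0
@protein	O	0	1	0	-	-	C	0
@protein	OXT	0	1	0	-	-	C	0
ARG	NE	1	0	0	bisector	CD,CZ	-	0
ARG	NH1	1	0	0	amide2	CZ,NE	-	0
ARG	NH2	1	0	0	amide2	CZ,NE	-	0
LYS	NZ	1	0	1	rotor3	CE,CD	-	0
ASN	ND2	1	0	0	amide2	CG,OD1	-	0
ASN	OD1	0	1	0	-	-	CG	0
GLN	NE2	1	0	0	amide2	CD,OE1	-	0
GLN	OE1	0	1	0	-	-	CD	0
ASP	OD1	0	1	0	-	-	CG	0
ASP	OD2	0	1	0	-	-	CG	0
GLU	OE1	0	1	0	-	-	CD	0
GLU	OE2	0	1	0	-	-	CD	0
HIS	ND1	1	1	0	bisector	CG,CE1	CG,CE1	0
HIS	NE2	1	1	0	bisector	CD2,CE1	CD2,CE1	0
SER	OG	1	1	1	rotor	CB,CA	CB	0
THR	OG1	1	1	1	rotor	CB,CA	CB	0
TYR	OH	1	1	1	rotor	CZ,CE1	CZ	0
TRP	NE1	1	0	0	bisector	CD1,CE2	-	0
CYS	SG	1	1	1	rotor	CB,CA	CB	0
MET	SD	0	1	0	-	-	CG,CE	0
A,DA	N6	1	0	0	amide2	C6,N1	-	0
A,DA	N1	1	1	0	bisector	C2,C6	C2,C6	0
A,DA	N3	1	1	0	bisector	C2,C4	C2,C4	0
A,DA	N7	0	1	0	-	-	C5,C8	0
C,DC	N4	1	0	0	amide2	C4,N3	-	0
C,DC	N3	1	1	0	bisector	C2,C4	C2,C4	0
C,DC	O2	0	1	0	-	-	C2	0
G,DG	N1	1	1	0	bisector	C2,C6	C2,C6	0
G,DG	N2	1	0	0	amide2	C2,N1	-	0
G,DG	N3	1	1	0	bisector	C2,C4	C2,C4	0
G,DG	N7	0	1	0	-	-	C5,C8	0
G,DG	O6	0	1	0	-	-	C6	0
U,DT	N3	1	1	0	bisector	C2,C4	C2,C4	0
U,DT	O2	0	1	0	-	-	C2	0
U,DT	O4	0	1	0	-	-	C4	0
@nt	OP1	0	1	0	-	-	P	0
@nt	OP2	0	1	0	-	-	P	0
@nt	O5'	1	1	1	rotor	C5',C4'	P,C5'	1
@nt	O4'	0	1	0	-	-	C1',C4'	0
@nt	O3'	1	1	1	rotor	C3',C4'	C3',P^+	1
@ribo	O2'	1	1	1	rotor	C2',C1'	C2'	0
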