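# Formal-charge model: net -1 on carboxylates (split across the two
# oxygens), +1 on LYS/ARG basic groups (ARG split across NH1/NH2),
# HIS neutral by default. Radii left empty fall back to the per-element
# table. Columns: residue_name, atom_name, charge, radius.
ASP	OD1	-0.5
ASP	OD2	-0.5
GLU	OE1	-0.5
GLU	OE2	-0.5
LYS	NZ	1.0
ARG	NH1	0.5
ARG	NH2	0.5
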