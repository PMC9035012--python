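# GROMOS 54B7-compatible SASA implicit-solvation parameters.
# R_i: atom radius (nm); p_i: overlap-correction parameter; sigma columns in
# kJ mol^-1 nm^-2 ("-" = undefined, raises on use in the energy term).
# class: three-class membership used by the simplified parameter set.
code	name	R_i	p_i	sigma_per_type	class	sigma_three_class	description
1	O	0.150	0.926	-7.2	polar	-7.3	Carbonyl oxygen (C=O)
2	OM	0.170	0.922	-21.7	charged	-23.3	Carboxyl oxygen (CO-)
3	OA	0.152	1.080	-7.0	polar	-7.3	Hydroxyl or sugar oxygen
4	OE	0.152	1.080	-	-	-	Ether or ester oxygen
5	OW	-	-	-	-	-	Water oxygen
6	N	0.155	1.028	0.0	-	0.0	Peptide nitrogen (NH)
7	NT	0.160	1.215	-4.0	polar	-7.3	Terminal nitrogen (NH2)
8	NL	0.160	1.215	-26.1	charged	-23.3	Terminal nitrogen (NH3)
9	NR	0.155	1.028	-4.5	polar	-7.3	Aromatic nitrogen
10	NZ	0.155	1.028	-13.3	charged	-23.3	Arg NH (NH2)
11	NE	0.155	1.028	0.0	-	0.0	Arg NE (NH)
12	C	0.172	1.554	0.0	-	0.0	Bare carbon
13	CH0	0.172	1.554	-	-	-	Bare sp3 carbon, 4 bound heavy atoms
14	CH1	0.180	1.276	3.8	hydrophobic	4.1	Aliphatic or sugar CH-group
15	CH2	0.190	1.045	5.0	hydrophobic	4.1	Aliphatic or sugar CH2-group
16	CH3	0.200	0.880	3.3	hydrophobic	4.1	Aliphatic CH3-group
17	CH4	-	-	-	-	-	Methane
18	CH2r	0.190	1.045	-	-	-	Aliphatic or sugar CH2-group in ring
19	CR1	0.180	1.073	4.5	hydrophobic	4.1	Aromatic CH-group
20	HC	0.110	1.128	0.0	-	-	Hydrogen bound to carbon
21	H	0.110	1.128	0.0	-	-	Hydrogen not bound to carbon
22	DUM	-	-	-	-	-	Dummy atom
23	S	0.180	1.121	0.0	-	-	Sulphur
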