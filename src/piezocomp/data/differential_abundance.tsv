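spot	accession	annotation	cog	da	direction	membrane_fraction
1	DESPIv2_11412	Periplasmic [NiFe] hydrogenase small subunit, HynA-1	C	2.6	increased	yes
2	DESPIv2_11809	Adenylylsulfate reductase, alpha subunit, AprA	C	2.4	increased	no
3	DESPIv2_12525	ATP synthase subunit b, AtpF	C	2.2	increased	yes
4	DESPIv2_20239	Nitroreductase	C	1.5	increased	no
5	DESPIv2_20445	Cobyrinic acid ac-diamide synthase	C	2.8	increased	no
6	DESPIv2_20246	Extracellular solute-binding protein family 1, PotD	E	2.7	increased	no
7	DESPIv2_10610	ABC transporter glutamine-binding protein GlnH	E	2.9	increased	no
8	DESPIv2_10611	ATP-binding component of ABC superfamily, AapP	E	1.6	increased	no
9	DESPIv2_10063	Polar amino acid ABC transporter subunit	E	4.5	increased	no
10	DESPIv2_10036	Extracellular solute-binding protein, family 5, DppA	E	1.9	increased	no
11	DESPIv2_12641	Extracellular ligand-binding receptor	E	1.9	increased	yes
12	DESPIv2_10448	Triosephosphate isomerase, TpiA	G	2.4	increased	no
13	DESPIv2_11436	Uncharacterized aldolase aq_1554	G	4.3	increased	no
14	DESPIv2_12350	Ribonuclease, Rne/Rng family	J	4.4	increased	no
15	DESPIv2_10222	Peptidoglycan-associated lipoprotein Pal	M	2.0	increased	yes
16	DESPIv2_12413	Outer membrane chaperone Skp (OmpH)	M	6.5	increased	yes
17	DESPIv2_12605	Putative AsmA family protein	M	3.4	increased	yes
18	DESPIv2_11075	Serine protease do-like DegP	O	9.6	increased	yes
19	DESPIv2_10232	Basic membrane lipoprotein	R	1.8	increased	no
20	DESPIv2_12411	Tetratricopeptide domain protein	R		increased	no
21	DESPIv2_10558	Conserved protein of unknown function	S	3.6	increased	no
22	DESPIv2_11823	Methyl-accepting chemotaxis sensory transducer	T	2.2	increased	yes
23	DESPIv2_10098	Outer membrane efflux protein	U	2.0	increased	yes
24	DESPIv2_10982	Conserved protein of unknown function		3.7	increased	no
25	DESPIv2_11808	Quinone-interacting membrane bound oxidoreductase, Flavin protein QmoA	C	3.9	decreased	no
26	DESPIv2_10343	Amino acid-binding ACT domain protein	E	2.4	decreased	no
27	DESPIv2_10492	Extracellular solute-binding protein family 3	E	2.8	decreased	yes
28	DESPIv2_11485	Extracellular solute-binding protein family 3	E	6.4	decreased	no
29	DESPIv2_12435	Alanine dehydrogenase	E	2.6	decreased	no
30	DESPIv2_12562	ATP phosphoribosyltransferase HisG	E	5.6	decreased	no
31	DESPIv2_10845	Ornithine carbamoyltransferase ArgF	F	1.8	decreased	no
32	DESPIv2_11386	TRAP dicarboxylate transporter DctP subunit	G	2.3	decreased	no
33	DESPIv2_10174	Modification methylase, HemK family	J	2.8	decreased	no
34	DESPIv2_11695	50 S ribosomal protein L19	J	3.8	decreased	no
35	DESPIv2_12480	Heat shock protein Hsp20	O	1.7	decreased	no
36	DESPIv2_20109	Conserved exported protein of unknown function	P	3.7	decreased	no
37	DESPIv2_11432	Putative Methyltransferase type 12	R	2.3	decreased	no
38	DESPIv2_12341	CBS domain-containing membrane protein	R	2.5	decreased	no
39	DESPIv2_10688	Sensor protein	T	2.6	decreased	no
40	DESPIv2_10745	Conserved protein of unknown function		2.4	decreased	no
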