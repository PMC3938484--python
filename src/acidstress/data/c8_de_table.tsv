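locus	gene	p	q	ratio	annotation
b1493	gadB	0.000	0.015	25.3	AR2 decarboxylase
b3509	hdeB	0.000	0.004	21.1	AR1 chaperone protein
b3238	yhcN	0.002	0.064	15.2	Acid response
b3510	hdeA	0.000	0.000	13.7	AR1 chaperone protein
b4439	micF	0.003	0.078	11.9	Antisense RNA regulator of OmpF porin
b3512	gadE	0.004	0.115	10.1	TA of AR2
b1492	gadC	0.000	0.013	9.3	AR2 antiporter
b3511	hdeD	0.001	0.053	8.7	AR1
b1480	sra	0.001	0.009	5.1	SP component of the 30S ribosomal subunit
b3508	yhiD	0.001	0.017	4.5	density-dependent acid resistance
b0812	dps	0.004	0.101	4.4	DNA-binding, iron-collecting, oxidative damage protection/repair
b3517	gadA	0.003	0.108	4.4	AR2 decarboxylase
b0485	ybaS	0.007	0.144	4.1	Glutaminase- acid shock inducible
b1531	marA	0.002	0.067	3.9	Multiple antibiotic resistance TR- organic solvents, oxidative stress
b2013	yeeE	0.009	0.157	3.8	Resistance to the DNA-damage
b0287	yagU	0.003	0.012	3.5	IMP- acid resistance
b1165	ymgA	0.002	0.003	3.5	Biofilm formation- rapid acid treatment
b3516	gadX	0.001	0.014	3.5	AR2 TR
b1112	bhsA	0.002	0.003	3.3	Influencing biofilm through hydrophobicity and SR
b2012	yeeD	0.010	0.106	3.0	Uncharacterized
b1164	ycgZ	0.006	0.107	2.9	Cold shock stimulon
b4554 (c4419)	yibT	0.001	0.056	2.8	Uncharacterized
b0814	ompX	0.004	0.017	2.8	Acid-induced OMP
b4376	osmY	0.001	0.023	2.8	Hyperosmotic stress
b3405	ompR	0.013	0.163	2.7	OMP TR
b3515	gadW	0.026	0.219	2.6	AR2 TR
b2924	mscS	0.001	0.028	2.4	IMP mechanosensitive (MS) channel; non-specific transporter
b0850	ybjC	0.003	0.011	2.4	marA/SoxS induced
b3024	ygiW	0.004	0.014	2.4	IMP transporter, SR
b0775 (c0855)	bioB	0.018	0.193	2.3	SAM-dependent biotin synthase
b2425	cysP	0.020	0.105	2.2	IMP Sulfate transporter
b1661	cfa	0.010	0.110	2.1	Cyclopropane fatty acid synthase
b3160	yhbW	0.000	0.015	2.0	Monooxygenase
b4077	gltP	0.024	0.213	2.0	Glutamate and aspartate transporter
b3458	livK	0.005	0.090	-2.0	leucine transporter
b1194	ycgR	0.002	0.018	-2.0	Flagellar motility
b1887	cheW	0.003	0.019	-2.0	Flagellar motors
b4484	cpxP	0.038	0.116	-2.1	TR, SR of cell envelope
b1075	flgD	0.009	0.032	-2.2	Flagella
b1941	fliI	0.007	0.031	-2.2	Flagellar export
b0455	ffs	0.035	0.220	-2.2	RNA, membrane protein assembly
b1942	fliJ	0.002	0.015	-2.5	Flagellar export
b1946	fliN	0.012	0.118	-2.5	Flagellar motor
b1921	fliZ	0.005	0.096	-2.5	TR flagella
b1922	fliA	0.000	0.000	-2.6	Flagella; sigma F factor
b1884	cheR	0.001	0.008	-2.8	Chemotaxis sensory transduction system
b1072	flgA	0.002	0.017	-3.0	Flagella assembly
b1742 (Z2774)	ves	0.010	0.157	-3.0	Cold shock stimulon
b1939	fliG	0.001	0.007	-3.2	Flagellar motor
b1945	fliM	0.000	0.001	-3.2	Flagellar motor
b1881	cheZ	0.012	0.173	-3.3	Chemotaxis sensory transduction system
b1078	flgG	0.024	0.223	-3.3	Flagellar motor
b4355	tsr	0.004	0.112	-3.4	Chemotaxis proteins
b1073	flgB	0.002	0.027	-3.4	Flagellar motor
b1937	fliE	0.005	0.045	-3.5	Flagella
b1076 (Z1714)	flgE	0.007	0.133	-3.6	Flagellar motor
b0557 (Z1878)	borD	0.001	0.011	-3.7	Magnesium stimulon
b1938	fliF	0.005	0.109	-3.7	Flagella
b1888	cheA	0.015	0.190	-3.7	chemotaxis protein
b1947	fliO	0.013	0.154	-3.8	Flagellar export
b1925	fliS	0.002	0.033	-3.8	Flagellar export
b1882	cheY	0.003	0.033	-3.9	Chemotaxis response regulator
b1071	flgM	0.001	0.018	-3.9	Flagella
b3525	yhjH	0.003	0.064	-3.9	flagellar motility
b1940 (c2357)	fliH	0.001	0.008	-3.9	flagella ATPase inhibitor
b1074	flgC	0.001	0.013	-4.0	Flagellar motor
b1944	fliL	0.000	0.015	-4.1	Flagella
b1943	fliK	0.001	0.003	-4.3	Flagellar export
b1886	tar	0.005	0.114	-4.3	Aspartate chemoreceptor
b1924	fliD	0.013	0.173	-4.4	Flagella
b1889	motB	0.004	0.086	-4.5	Flagellar motor
b1070	flgN	0.000	0.000	-5.1	Flagellar export
b1923	fliC	0.003	0.095	-5.4	Flagella
b1076	flgE	0.004	0.106	-5.8	Flagellar motor
b1890	motA	0.000	0.000	-6.0	Flagellar motor
b1566	flxA	0.000	0.000	-6.3	Prophage
b1083	flgL	0.002	0.083	-9.3	Flagella
b0929	ompF	0.000	0.022	-16.0	Transport of sugars, ions, and amino acids <600 daltons
b0553	nmpC	0.002	0.069	-16.3	OMP porin associated with the peptidoglycan
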