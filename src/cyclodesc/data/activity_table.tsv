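#label	protein	subfamily	anthelmintic_uM	cytotoxic_uM
M1	kB1	Mobius	2.48	6.9
M2	[G1K]-kB1	Mobius	0.5	-
M3	[L2K]-kB1	Mobius	6.2	-
M4	[P3K]-kB1	Mobius	>11.5	-
M5	[V4K]-kB1	Mobius	11.1	-
M6	[G6K]-kB1	Mobius	>11.5	-
M7	[E7K]-kB1	Mobius	>11.5	-
M8	[T8K]-kB1	Mobius	>11.5	-
M9	[V10K]-kB1	Mobius	>11.5	-
M10	[G11K]-kB1	Mobius	5.3	-
M11	[G12K]-kB1	Mobius	>11.5	-
M12	[T13K]-kB1	Mobius	2.8	-
M13	[N15K]-kB1	Mobius	>11.5	-
M14	[T16K]-kB1	Mobius	>11.5	-
M15	[P17K]-kB1	Mobius	3.6	-
M16	[G18K]-kB1	Mobius	1.1	-
M17	[T20K]-kB1	Mobius	0.9	-
M18	[T20K, G1K]-kB1	Mobius	0.4	-
M19	[T20K, S22K]-kB1	Mobius	0.7	-
M20	[T20K, N29K]-kB1	Mobius	0.4	-
M21	[T20K, N29K, G1K]-kB1	Mobius	0.2	-
M22	[S22K]-kB1	Mobius	2.3	-
M23	[W23K]-kB1	Mobius	>11.5	-
M24	[V25K]-kB1	Mobius	>11.5	-
M25	[T27K]-kB1	Mobius	1.6	-
M26	[R28K]-kB1	Mobius	3.9	-
M27	[N29K]-kB1	Mobius	0.4	-
M28	kB2	Mobius	1.59	2.6
M29	kB6	Mobius	0.87	-
M30	kB7	Mobius	6.29	29
M31	kB13	Mobius	-	3.8
M32	cyH3	Mobius	0.85	-
M33	cyO14	Mobius	0.41	-
M34	cyO15	Mobius	0.38	-
M35	cyO16	Mobius	0.27	-
M36	cyO24	Mobius	1.74	-
M37	vaby A	Mobius	-	7.6
M38	vaby D	Mobius	-	2.8
M39	varv A	Mobius	1.13	8.2
M40	[Cdr]-varv A	Mobius	-	9.1
M41	[Cdr, Mee]-varv A	Mobius	-	46
M42	[Mee]-varv A	Mobius	-	34
M43	varv E	Mobius	0.9	4
M44	varv F	Mobius	-	7.1
M45	vibi D	Mobius	-	>30
B1	circulin A	bracelet	-	-
B2	circulin B	bracelet	-	-
B3	cyO1	bracelet	2.82	-
B4	cyO2	bracelet	0.12	1.03
B5	[Cdr]-cyO2	bracelet	-	0.95
B6	[Cdr, Ack]-cyO2	bracelet	-	5.1
B7	[Mee]-cyO2	bracelet	0.76	36
B8	[Ack]-cyO2	bracelet	2.3	2.3
B9	[Kyw]-cyO2	bracelet	-	5.2
B10	cyO3	bracelet	0.21	-
B11	cyO8	bracelet	0.24	-
B12	cyO13	bracelet	0.21	-
B13	cyO19	bracelet	-	0.52
B14	cyY4	bracelet	2.01	-
B15	cyY5	bracelet	2.28	-
B16	psyle E	bracelet	-	0.76
B17	vhl-1	bracelet	2.06	-
B18	vibi E	bracelet	-	3.2
B19	vibi G	bracelet	-	0.96
B20	vibi H	bracelet	-	1.6
B21	vitri A	bracelet	-	0.6
B22	vodo O	bracelet	-	3.2
H1	[W23K, P24N, V25K]-kB1	hybrid	-	-
H2	[P24K]-kB1	hybrid	-	-
H3	[P24D, V25K]-kB1	hybrid	-	-
H4	kB8	hybrid	-	18
H5	psyle A	hybrid	-	2
H6	tricyclon A	hybrid	-	-
L1	psyle C	linear	-	3.5
L2	violacin A	linear	-	-
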