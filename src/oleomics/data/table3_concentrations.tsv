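compound	K	D	F	J	M	L	C	O	E	I	N	H	A	G
Quinic acid	0.19-0.21	0.57-0.81	0.11-0.34	0.35-0.57	1.11-1.51	0.73-0.77	11.52-15.3	<LOQ	0.64-0.67	0.45-0.7	<LOQ	<LOQ	0.4-0.65	74.84-79.94
Malic acid	<LOQ	LOQ-0.14	<LOQ	0.18-0.22	0.75-0.82	0.48-0.54	2.86-3.49	<LOQ	0.95-1.3	0.39-0.41	<LOQ	<LOQ	0.21-0.39	19.7-22.88
Citric acid	<LOQ	ND-<LOQ	<LOQ	0.85-0.89	0.27-0.27	0.3-0.34	1.08-1.2	<LOQ	0.58-0.7	0.57-0.59	<LOQ	LOQ-0.06	0.4-0.45	19.19-21.08
Isocitric acid	ND	ND-<LOQ	ND-<LOQ	0-0.01	0.06-0.06	0-0	0.12-0.2	<LOQ	0.01-0.02	0.06-0.07	<LOQ	<LOQ	0.02-0.04	0.3-0.32
Succinic acid	<LOQ	<LOQ	<LOQ	<LOQ	0.07-0.09	<LOQ	0.21-0.28	<LOQ	<LOQ	0.55-0.62	<LOQ	<LOQ	<LOQ	0.5-0.54
Sorbitol	0.14-0.14	0.13-0.24	0.1-0.22	0.08-0.1	0.11-0.13	0.49-0.49	0.87-0.93	0.08-0.09	0.06-0.07	0.7-0.77	<LOQ	<LOQ	0.08-0.1	2-2.02
Trihydroxyoctadecenoic acid (I)	ND	ND-<LOQ	ND-<LOQ	ND	ND	ND	ND	ND	ND-<LOQ	ND	ND	ND	ND-0.03	0.04-0.05
Trihydroxyoctadecenoic acid (II)	ND-<LOQ	ND-<LOQ	ND-<LOQ	<LOQ	<LOQ	0.01-0.01	ND-<LOQ	ND-<LOQ	<LOQ	0-0.01	ND	ND	0.01-0.02	0-0.01
Trihydroxyoctadecenoic acid (III)	ND-<LOQ	ND-<LOQ	<LOQ	<LOQ	0.01-0.02	0.03-0.03	ND-0.02	0.01-0.02	0.05-0.05	0.18-0.22	ND	ND	0.01-0.01	0.03-0.05
Verbascoside	ND	ND-0.03	ND-0.02	0.02-0.04	0.14-0.16	0.09-0.1	2.8-3.05	ND-0.02	0.78-0.81	0.75-3.7	ND-0.02	ND-0.03	47.43-51.19	16.96-18.26
Hydroxy-verbascoside (I)	ND	ND	ND	ND	ND-0.02	ND	0.06-0.07	ND	0.15-0.16	0.07-0.18	ND	ND-0.04	2.99-3.1	0.75-0.88
Hydroxy-verbascoside (II)	ND	ND	ND	ND	ND-0.03	ND	0.38-0.43	ND	0.06-0.06	0.05-0.12	ND	ND	3.09-3.17	0.75-0.83
3,4-Dihydroxy-phenylglycol	<LOQ	<LOQ	<LOQ	0.07-0.08	0.01-0.02	0.11-0.11	0.01-0.02	<LOQ	ND-<LOQ	0.11-0.13	<LOQ	0.12-0.14	0.3-0.38	0.1-0.1
Hydroxytyrosol	<LOQ	<LOQ	<LOQ	0.14-0.16	0.2-0.27	0.05-0.06	0.13-0.17	0.09-0.13	LOQ-0.06	17.15-21.46	5.99-8.82	74.83-88.2	14.94-20.06	9.14-10.14
Hydroxytyrosol glucoside (I)	ND-<LOQ	<LOQ	<LOQ	LOQ-0.02	<LOQ	<LOQ	0.5-0.64	<LOQ	0.12-0.17	0.58-0.66	LOQ-0.47	0.17-0.2	1.71-3.03	0.55-0.75
Hydroxytyrosol glucoside (II)	<LOQ	<LOQ	<LOQ	LOQ-0.02	0.07-0.1	0.2-0.21	2.2-2.39	<LOQ	0.18-0.26	0.78-0.92	LOQ-0.17	0.08-0.12	1.38-2.05	0.56-0.69
Tyrosol	0.04-0.04	0.04-0.05	0.04-0.04	ND	0.03-0.05	0.05-0.06	ND-0.21	0.07-0.08	ND-0.07	2.28-2.66	ND	2.17-2.38	4.93-5.8	3.2-3.25
Tyrosol glucoside	ND	ND-<LOQ	ND-<LOQ	ND	0.33-0.37	ND	1.76-2.35	ND	0.57-0.77	0.4-0.56	ND	ND	10.73-11.98	4.64-6.4
Oleuropein	<LOQ	LOQ-0.01	<LOQ	0.13-0.14	0.42-0.61	0.37-0.39	16.49-19.22	<LOQ	15.64-17.4	71.76-79.09	<LOQ	LOQ-0.08	3.9-4.86	0.17-0.22
Oleuropein isomer (I)	<LOQ	ND-<LOQ	<LOQ	ND-<LOQ	ND-<LOQ	ND	0.01-0.05	ND-<LOQ	ND-0.08	0.21-0.28	<LOQ	ND-<LOQ	0.01-0.01	LOQ-0.01
Oleuropein isomer (II)	<LOQ	<LOQ	<LOQ	LOQ-0.01	<LOQ	<LOQ	0.72-0.79	ND-<LOQ	0.21-0.26	2.93-3.77	<LOQ	<LOQ	0.11-0.13	0.06-0.07
Elenolic acid	<LOQ	<LOQ	ND	0.01-0.01	<LOQ	0.03-0.04	<LOQ	<LOQ	<LOQ	0.1-0.11	ND-<LOQ	ND	1.21-1.37	0.41-0.45
DEDA	<LOQ	<LOQ	LOQ-0.51	<LOQ	<LOQ	<LOQ	<LOQ	LOQ-0.01	<LOQ	0.24-0.26	LOQ-0.17	2.78-3.16	0.73-0.83	1.84-2.13
Hydroxy-DEDA	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	0.19-0.21	<LOQ	<LOQ	<LOQ	<LOQ	LOQ-0.04	0.09-0.09	0.14-0.16	1.59-1.76
DEDA hydrated (I)	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	0.11-0.12	LOQ-0.12	0.94-1.33	0.09-0.1	0.06-0.09
DEDA hydrated (II)	ND-<LOQ	ND-<LOQ	ND-<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	<LOQ	0.11-0.13	<LOQ	<LOQ
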