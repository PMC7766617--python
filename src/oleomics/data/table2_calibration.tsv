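analyte	detector	ldr_lo_mg_l	ldr_hi_mg_l	intercept	slope	r2	intra_day_rsd	inter_day_rsd	repeatability_rsd
Quinic acid	MS	10	100	2284463	146048	0.989	6.78	10.87	5.38
Malic acid	MS	10	100	1649636	32379	0.992	7.51	14.90	6.68
Isocitric acid	MS	0.2	50	226679	204797	0.993	7.74	12.54	9.38
Citric acid	MS	5	100	1484339	213678	0.995	7.00	16.25	5.90
Succinic acid	MS	5	100	769682	66403	0.991	3.55	14.35	3.09
Sorbitol	MS	2	100	968312	88135	0.972	4.59	13.94	2.07
3,4-Dihydroxy-phenylglycol	MS	0.2	50	262381	91393	0.986	8.99	18.55	2.92
Hydroxytyrosol	MS	2	100	2082530	253685	0.988	10.41	5.41	8.30
Oleuropein	MS	0.5	50	1004848	695049	0.991	4.00	5.25	4.04
Tyrosol	DAD	2	1505	-16214	5499	1.000	1.52	3.65	8.19
Tyrosol glucoside	DAD	5	100	-111	2334	1.000	2.26	2.85	9.81
Verbascoside	DAD	0.5	1536	-23591	14737	1.000	0.77	1.81	9.48
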