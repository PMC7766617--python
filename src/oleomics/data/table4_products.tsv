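product	plant_part	form	daily_dose_label	daily_dose_g	other_extracts	extraction
K	buds	Drops	100 drops (5.28 g)	5.28	no	glyceric macerate
D	buds	Drops	80 drops (2.13 g)	2.13	no	glyceric macerate
F	buds	Drops	75 drops (2.70 g)	2.70	no	glyceric macerate
J	leaves	Liquid	70 mL (72.8 g)	72.8	yes	liquid extract
M	leaves	Drops	75 drops (1.98 g)	1.98	yes	liquid extract
L	leaves	Drops	75 drops (1.98 g)	1.98	no	liquid extract
C	leaves	Capsules	4 cps (2 g)	2	yes	dry extract
O	leaves and fruit	Raw material	400 mg (0.4 g)	0.4	no	dry extract
E	leaves and fruit	Capsules	2 cps (1.2 g)	1.2	yes	dry extract
I	leaves and fruit	Raw material	400 mg (0.4 g)	0.4	no	dry extract
N	fruit	Capsules	2 cps (1.28 g)	1.28	no	dry extract
H	fruit	Raw material	25 mg (0.025 g)	0.025	no	dry extract
A	fruit	Raw material	400 mg (0.4 g)	0.4	no	dry extract
G	fruit	Raw material	400 mg (0.4 g)	0.4	no	dry extract
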