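formin	fh2_residue	fh2_domain	actin_residue	actin_subunit	occupancy_A_7mer_200ns	occupancy_B_7mer_500ns	occupancy_C_5mer_350ns
Cdc12	K1068	FHL	D25	A2	78.2	76.9	86.5
Cdc12	E1090	FHL	R147	A2	NA	63.1	13.1
Cdc12	E1093	FHL	R147	A2	99.4	NA	NA
Cdc12	K1099	FHL	E167	A2	NA	NA	41.2
Cdc12	K1105	FHL	E167	A2	NA	52.6	77.1
Cdc12	K1107	FHL	E167	A2	41.5	NA	NA
Cdc12	K1068	FHT	D25	A3	95.2	70.7	82.4
Cdc12	K1072	FHT	D25	A3	64.3	71.4	85.3
Cdc12	K1072	FHT	D24	A3	NA	15.6	12.8
Cdc12	E1093	FHT	R147	A3	94.8	97.3	99.8
Cdc12	K1099	FHT	E167	A3	NA	47.2	18.1
Bni1	E1463	FHL	R147	A2	83.6	89.5	88.6
Bni1	R1423	FHL	E167	A2	0.401	0.541	NA
Bni1	E1463	FHT	R147	A3	90.0	88.5	93.8
Bni1	K1467	FHT	E167	A3	97.4	95.7	NA
mDia1	R851	FHL	D25	A2	97.8	93.5	NA
mDia1	E871	FHL	R147	A2	8.42	18.8	NA
mDia1	K879	FHL	E167	A2	25.3	3.69	NA
mDia1	K838	FHT	E167	A3	98.6	98.6	25.7
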