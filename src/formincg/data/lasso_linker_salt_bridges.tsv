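formin	fh2_residue	fh2_domain	actin_residue	actin_subunit	occupancy_7mer_200ns
Cdc12	R990	FHL-lasso	D363	A2	100.0
Cdc12	K992	FHT-lasso	E125	A1	99.6
Cdc12	K1038	FHL-linker	E99	A2	71.5
Cdc12	K1041	FHL-linker	E100	A2	52.5
Cdc12	K1045	FHL-linker	E2	A2	72.3
Cdc12	K1045	FHL-linker	D3	A2	93.2
Cdc12	K1046	FHL-linker	E4	A2	50.3
Cdc12	K1038	FHT-linker	D363	A1	20.6
Bni1	K1357	FHL-lasso	D363	A2	85.2
Bni1	K1357	FHT-lasso	D363	A1	23.0
Bni1	K1359	FHT-lasso	E125	A1	99.2
Bni1	R1402	FHL-linker	E99	A2	99.4
Bni1	E1403	FHL-linker	K359	A2	95.0
Bni1	K1410	FHL-linker	E4	A2	24.0
Bni1	K1410	FHL-linker	E100	A2	81.8
Bni1	K1412	FHL-linker	D3	A2	57.5
Bni1	R1402	FHT-linker	D363	A1	98.4
mDia1	R764	FHL-lasso	D363	A2	23.4
mDia1	K807	FHL-linker	E125	A2	49.9
mDia1	K813	FHL-linker	E4	A2	37.9
mDia1	K813	FHL-linker	E99	A2	20.4
mDia1	K826	FHL-linker	D3	A2	70.9
mDia1	K826	FHL-linker	E2	A2	43.3
mDia1	K827	FHL-linker	E2	A2	13.2
mDia1	K828	FHL-linker	E2	A2	11.4
mDia1	K807	FHT-linker	E125	A1	23.0
mDia1	K810	FHT-linker	E83	A1	43.7
mDia1	K810	FHT-linker	E125	A1	46.7
mDia1	K813	FHT-linker	D51	A1	99.0
mDia1	E816	FHT-linker	R37	A1	96.8
mDia1	K828	FHT-linker	E2	A3	25.1
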