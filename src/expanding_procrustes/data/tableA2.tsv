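subject	group	ru_deg	rf_deg	rh_deg	lu_deg	lf_deg	lh_deg
G1.01	1	19.3	53.0	88.6	8.9	0.4	2.8
G1.02	1	30.2	54.7	89.6	9.5	0.1	-8.7
G1.03	1	59.8	89.2	82.5	11.7	-13.1	4.6
G1.04	1	54.3	51.2	86.7	8.5	5.2	-1.0
G1.05	1	34.5	58.5	82.6	11.6	-5.9	11.4
G1.06	1	47.6	42.5	89.0	6.6	-6.4	7.8
G1.07	1	22.5	89.3	88.8	10.1	12.3	18.5
G1.08	1	34.0	59.4	88.7	-5.2	-14.9	17.7
G1.09	1	32.1	63.8	87.3	9.9	-0.8	16.5
G1.10	1	28.3	62.0	89.1	-5.8	-3.7	14.2
G2.01	2	44.5	83.4	54.3	83.7	58.0	45.1
G2.02	2	16.3	16.1	88.0	0.0	22.2	4.4
G2.03	2	38.6	55.2	88.8	3.2	-18.1	10.3
G2.04	2	38.0	84.9	86.2	23.3	-20.4	11.7
G2.05	2	32.2	54.0	73.4	8.3	-13.8	8.9
G2.06	2	12.8	59.1	89.6	46.1	26.0	18.1
G2.07	2	32.6	80.0	87.5	13.7	-4.5	13.6
G2.08	2	38.6	69.8	81.8	34.7	-16.1	12.0
G2.09	2	18.2	37.6	89.8	16.2	7.2	22.2
G2.10	2	27.3	36.2	82.5	6.2	-7.9	13.0
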