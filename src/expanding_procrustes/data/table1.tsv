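subject	group	age_years	gender	arm_length_cm	eye_height_cm
G1.01	1	24	M	67	146
G1.02	1	20	M	78	154
G1.03	1	24	M	75	142
G1.04	1	29	M	73	151
G1.05	1	27	M	71	163
G1.06	1	24	M	77	154
G1.07	1	23	F	75	148
G1.08	1	21	F	69	140
G1.09	1	20	F	72	140
G1.10	1	22	F	75	145
G2.01	2	63	F	70	137
G2.02	2	57	F	61	124
G2.03	2	58	M	76	138
G2.04	2	56	F	71	147
G2.05	2	57	F	69	127
G2.06	2	71	M	83	154
G2.07	2	61	M	69	143
G2.08	2	61	M	72	143
G2.09	2	39	M	73	162
G2.10	2	36	M	72	150
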