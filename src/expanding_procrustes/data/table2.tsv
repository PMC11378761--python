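subject	group	task1_time_s	task2_time_s	task3_time_s
G1.01	1	3.18	15.82	5.54
G1.02	1	4.00	17.45	6.63
G1.03	1	2.89	18.10	6.78
G1.04	1	3.85	18.23	6.27
G1.05	1	4.34	18.04	5.99
G1.06	1	2.30	15.93	5.34
G1.07	1	2.28	16.52	4.58
G1.08	1	3.89	14.78	5.15
G1.09	1	2.19	11.18	5.55
G1.10	1	3.71	17.56	7.19
G2.01	2	9.35	17.52	4.15
G2.02	2	6.07	22.81	8.48
G2.03	2	6.09	18.95	6.92
G2.04	2	4.14	18.57	4.83
G2.05	2	2.57	12.47	4.44
G2.06	2	4.74	17.52	5.24
G2.07	2	4.60	14.52	5.39
G2.08	2	4.60	20.35	5.27
G2.09	2	3.72	17.84	7.41
G2.10	2	3.65	19.56	7.10
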