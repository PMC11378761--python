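task	subject	group	uf_di	uh_di	fh_di	uf_pct	uh_pct	fh_pct
task1	G1.01	1	0.12	0.29	0.13	0.0	0.0	80.0
task1	G1.02	1	0.13	0.12	0.10	26.7	73.3	86.7
task1	G1.03	1	0.27	0.20	0.11	0.0	0.0	45.5
task1	G1.04	1	0.05	0.15	0.12	18.2	36.4	27.3
task1	G1.05	1	0.14	0.13	0.06	46.7	73.3	80.0
task1	G1.06	1	0.00	0.09	0.16	12.5	37.5	75.0
task1	G1.07	1	0.10	0.10	0.54	0.0	0.0	0.0
task1	G1.08	1	0.45	0.70	0.46	0.0	33.3	33.3
task1	G1.09	1	0.09	0.16	0.01	0.0	25.0	25.0
task1	G1.10	1	0.44	0.09	0.07	15.4	53.8	69.2
task2b	G1.01	1	0.46	0.58	0.48	0.0	0.0	25.0
task2b	G1.02	1	0.69	0.68	0.79	24.5	0.0	24.5
task2b	G1.03	1	0.52	0.82	0.91	24.8	0.0	0.0
task2b	G1.04	1	0.44	0.39	0.62	24.5	24.5	0.0
task2b	G1.05	1	0.63	0.60	0.43	25.2	0.0	25.2
task2b	G1.06	1	0.53	0.77	0.80	25.0	25.0	25.0
task2b	G1.07	1	0.58	0.53	0.59	25.3	0.0	25.3
task2b	G1.08	1	0.85	0.59	0.66	0.0	26.6	25.0
task2b	G1.09	1	0.64	0.49	0.37	25.0	0.0	25.0
task2b	G1.10	1	0.28	0.43	0.41	24.6	0.0	24.6
task2u	G1.01	1	0.46	0.56	0.49	0.0	0.0	24.8
task2u	G1.02	1	0.70	0.77	0.80	24.7	0.0	24.7
task2u	G1.03	1	0.53	0.84	0.91	24.7	0.0	0.0
task2u	G1.04	1	0.48	0.41	0.58	24.8	24.8	24.8
task2u	G1.05	1	0.59	0.58	0.46	25.0	0.0	25.0
task2u	G1.06	1	0.56	0.77	0.80	25.0	25.0	25.0
task2u	G1.07	1	0.60	0.63	0.58	24.9	0.0	24.9
task2u	G1.08	1	0.60	0.75	0.67	25.2	25.2	25.2
task2u	G1.09	1	0.68	0.46	0.38	25.0	25.0	25.0
task2u	G1.10	1	0.29	0.36	0.42	24.5	0.0	24.5
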