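task	subject	group	uf_di	uh_di	fh_di	uf_pct	uh_pct	fh_pct
task1	G2.01	2	0.20	0.12	0.80	0.0	90.9	0.0
task1	G2.02	2	0.40	0.46	0.17	18.8	0.0	31.3
task1	G2.03	2	0.20	0.48	0.27	26.1	30.4	30.4
task1	G2.04	2	0.59	0.69	0.32	20.0	0.0	33.3
task1	G2.05	2	0.73	0.10	0.11	0.0	33.3	44.4
task1	G2.06	2	0.29	0.49	0.76	0.0	31.3	0.0
task1	G2.07	2	0.55	0.17	0.85	0.0	29.4	0.0
task1	G2.08	2	0.55	0.17	0.85	0.0	29.4	0.0
task1	G2.09	2	0.14	0.45	0.11	0.0	0.0	64.3
task1	G2.10	2	0.01	0.16	0.29	15.4	0.0	30.8
task2b	G2.01	2	0.77	0.60	0.79	25.2	25.2	25.2
task2b	G2.02	2	0.51	0.57	0.61	25.1	0.0	0.0
task2b	G2.03	2	0.46	0.41	0.48	25.0	25.0	25.0
task2b	G2.04	2	0.63	0.76	0.64	25.0	0.0	25.0
task2b	G2.05	2	0.91	0.66	0.64	0.0	25.3	25.3
task2b	G2.06	2	0.65	0.78	0.54	0.0	0.0	24.3
task2b	G2.07	2	0.69	0.82	0.75	0.0	0.0	24.2
task2b	G2.08	2	0.36	0.30	0.79	0.0	0.0	0.0
task2b	G2.09	2	0.71	0.72	0.70	0.0	0.0	25.8
task2b	G2.10	2	0.81	0.66	0.74	24.9	24.9	24.9
task2u	G2.01	2	0.76	0.64	0.79	25.1	25.1	25.1
task2u	G2.02	2	0.53	0.57	0.63	25.1	0.0	0.0
task2u	G2.03	2	0.53	0.41	0.55	25.1	25.1	25.1
task2u	G2.04	2	0.65	0.78	0.70	24.7	24.7	24.7
task2u	G2.05	2	0.87	0.66	0.61	0.0	25.0	25.0
task2u	G2.06	2	0.69	0.77	0.65	0.0	25.1	25.1
task2u	G2.07	2	0.53	0.90	0.82	0.0	0.0	24.8
task2u	G2.08	2	0.40	0.41	0.79	0.0	0.0	0.0
task2u	G2.09	2	0.66	0.75	0.76	0.0	0.0	24.7
task2u	G2.10	2	0.76	0.64	0.71	24.8	24.8	24.8
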