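subject	group	uf_t1	uf_t2	uf_t3	uh_t1	uh_t2	uh_t3	fh_t1	fh_t2	fh_t3
G1.01	1	0.42	0.37	0.12	0.76	0.57	0.21	0.56	0.53	0.10
G1.02	1	0.60	0.79	0.26	0.62	0.53	0.20	0.49	0.73	0.15
G1.03	1	0.65	0.78	0.35	0.80	0.63	0.28	0.73	0.85	0.35
G1.04	1	0.50	0.32	0.20	0.80	0.38	0.28	0.83	0.47	0.35
G1.05	1	0.70	0.82	0.33	0.96	0.72	0.38	0.85	0.74	0.36
G1.06	1	0.87	0.53	0.29	0.93	0.41	0.45	0.88	0.55	0.25
G1.07	1	0.70	0.51	0.62	0.78	0.65	0.38	0.77	0.62	0.64
G1.08	1	0.52	0.78	0.37	0.87	0.37	0.44	0.85	0.74	0.21
G1.09	1	0.52	0.47	0.47	0.84	0.63	0.40	0.69	0.58	0.46
G1.10	1	0.41	0.27	0.47	0.56	0.51	0.32	0.38	0.55	0.39
G2.01	2	1.00	0.96	0.35	0.96	0.68	0.28	1.00	0.93	0.33
G2.02	2	0.67	0.40	0.16	0.84	0.63	0.21	0.85	0.79	0.26
G2.03	2	0.37	0.40	0.80	0.69	0.35	0.63	0.57	0.57	0.36
G2.04	2	0.65	0.71	0.41	0.83	0.57	0.63	0.84	0.79	0.54
G2.05	2	0.37	0.92	0.38	0.72	0.73	0.44	0.48	0.91	0.19
G2.06	2	0.68	0.87	0.68	0.51	0.59	0.27	0.76	0.92	0.50
G2.07	2	0.58	0.83	0.24	0.89	0.86	0.26	0.85	0.83	0.38
G2.08	2	0.58	0.59	0.82	0.89	0.94	0.89	0.85	0.94	0.90
G2.09	2	0.95	0.57	0.47	0.87	0.84	0.38	0.99	0.79	0.70
G2.10	2	0.69	0.50	0.31	0.81	0.28	0.19	0.87	0.53	0.30
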