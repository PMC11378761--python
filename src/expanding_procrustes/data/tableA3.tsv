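subject	group	u_t1	u_t2	u_t3	f_t1	f_t2	f_t3	h_t1	h_t2	h_t3
G1.01	1	0.09	0.12	0.72	0.31	0.48	0.60	0.58	0.63	0.72
G1.02	1	0.13	0.05	0.73	0.97	0.97	0.68	0.81	0.52	0.73
G1.03	1	0.26	0.09	0.84	0.69	0.87	0.99	0.54	0.81	0.84
G1.04	1	0.35	0.17	0.70	0.75	0.63	0.73	0.85	0.98	0.72
G1.05	1	0.14	0.48	0.75	0.20	0.57	0.63	0.91	0.61	0.73
G1.06	1	0.28	0.11	0.74	0.90	0.80	0.67	0.69	0.65	0.80
G1.07	1	0.69	0.22	0.66	0.50	0.98	0.89	0.58	0.67	0.63
G1.08	1	0.19	0.16	0.59	0.91	0.93	0.80	0.85	0.87	0.68
G1.09	1	0.08	0.09	0.85	0.48	0.65	0.94	0.94	0.58	0.69
G1.10	1	0.26	0.15	0.54	0.48	0.42	0.49	0.71	0.60	0.55
G2.01	2	0.81	0.60	0.73	1.00	0.92	0.62	0.84	0.08	0.63
G2.02	2	0.16	0.39	0.53	0.55	0.99	0.97	0.94	0.71	0.58
G2.03	2	0.04	0.06	0.78	0.10	0.36	0.73	0.35	0.46	0.69
G2.04	2	0.22	0.55	0.76	0.71	0.82	0.79	0.68	0.58	0.87
G2.05	2	0.18	0.15	0.57	0.42	0.87	0.50	0.72	0.91	0.59
G2.06	2	0.19	0.16	0.59	0.91	0.93	0.80	0.85	0.87	0.68
G2.07	2	0.14	0.52	0.56	0.97	0.96	0.53	0.49	0.64	0.70
G2.08	2	0.14	0.18	0.90	0.97	0.93	1.00	0.49	0.95	0.90
G2.09	2	0.31	0.18	0.84	0.93	0.65	0.99	0.79	0.70	0.94
G2.10	2	0.31	0.06	0.69	0.97	0.93	0.73	0.94	0.50	0.68
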