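task	subject	group	u_di	f_di	h_di	u_pct	f_pct	h_pct
task1	G2.01	2	0.03	0.44	0.79	97	33	0
task1	G2.02	2	0.05	0.22	0.39	88	31	38
task1	G2.03	2	0.03	0.04	0.09	96	96	96
task1	G2.04	2	0.77	0.06	0.14	0	87	93
task1	G2.05	2	0.01	0.07	0.05	33	78	89
task1	G2.06	2	0.53	0.38	0.87	0	31	0
task1	G2.07	2	0.33	0.36	0.18	29	21	29
task1	G2.08	2	0.13	0.44	0.33	82	13	29
task1	G2.09	2	0.05	0.04	0.31	86	86	29
task1	G2.10	2	0.14	0.29	0.26	69	31	31
task2b	G2.01	2	0.78	0.60	0.30	0	0	25
task2b	G2.02	2	0.28	0.61	0.55	25	0	0
task2b	G2.03	2	0.06	0.38	0.27	99	25	26
task2b	G2.04	2	0.23	0.18	0.84	25	25	0
task2b	G2.05	2	0.17	0.74	0.80	26	0	0
task2b	G2.06	2	0.35	0.33	0.77	24	26	0
task2b	G2.07	2	0.25	0.67	0.70	24	0	0
task2b	G2.08	2	0.15	0.68	0.87	29	0	0
task2b	G2.09	2	0.63	0.69	0.71	0	0	0
task2b	G2.10	2	0.16	0.32	0.43	25	25	25
task2u	G2.01	2	0.81	0.61	0.33	0	0	25
task2u	G2.02	2	0.29	0.64	0.58	25	0	0
task2u	G2.03	2	0.06	0.43	0.37	100	25	25
task2u	G2.04	2	0.27	0.19	0.77	25	25	0
task2u	G2.05	2	0.19	0.87	0.87	26	0	0
task2u	G2.06	2	0.39	0.47	0.78	25	0	0
task2u	G2.07	2	0.40	0.59	0.84	25	0	0
task2u	G2.08	2	0.14	0.64	0.86	30	0	0
task2u	G2.09	2	0.64	0.70	0.68	0	0	0
task2u	G2.10	2	0.15	0.31	0.41	78	25	25
task3	G2.01	2	0.34	0.09	0.13	25	30	40
task3	G2.02	2	0.28	0.46	0.24	15	0	15
task3	G2.03	2	0.23	0.22	0.18	13	13	13
task3	G2.04	2	0.59	0.46	0.16	0	0	33
task3	G2.05	2	0.53	0.08	0.14	0	31	14
task3	G2.06	2	0.42	0.56	0.56	30	0	0
task3	G2.07	2	0.32	0.24	0.23	20	20	20
task3	G2.08	2	0.14	0.07	0.61	8	15	0
task3	G2.09	2	0.14	0.60	0.25	30	0	14
task3	G2.10	2	0.14	0.35	0.40	22	13	13
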