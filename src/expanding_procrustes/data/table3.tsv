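task	subject	group	u_di	f_di	h_di	u_pct	f_pct	h_pct
task1	G1.01	1	0.05	0.04	0.03	80	80	90
task1	G1.02	1	0.26	0.24	0.06	33	33	40
task1	G1.03	1	0.15	0.14	0.83	45	45	0
task1	G1.04	1	0.60	0.13	0.20	0	27	45
task1	G1.05	1	0.03	0.04	0.09	93	93	87
task1	G1.06	1	0.15	0.05	0.11	38	50	38
task1	G1.07	1	0.04	0.32	0.15	88	25	25
task1	G1.08	1	0.08	0.61	0.03	83	33	75
task1	G1.09	1	0.06	0.28	0.01	38	50	25
task1	G1.10	1	0.10	0.12	0.08	54	50	92
task2b	G1.01	1	0.47	0.36	0.76	0	25	0
task2b	G1.02	1	0.15	0.63	0.74	24	0	0
task2b	G1.03	1	0.14	0.79	0.63	99	0	0
task2b	G1.04	1	0.51	0.50	0.70	0	0	0
task2b	G1.05	1	0.22	0.24	0.57	26	25	0
task2b	G1.06	1	0.08	0.78	0.51	99	0	0
task2b	G1.07	1	0.46	0.56	0.52	0	0	0
task2b	G1.08	1	0.40	0.66	0.55	25	0	0
task2b	G1.09	1	0.52	0.37	0.58	0	25	0
task2b	G1.10	1	0.15	0.16	0.50	56	25	0
task2u	G1.01	1	0.47	0.34	0.69	0	25	0
task2u	G1.02	1	0.08	0.64	0.86	99	0	0
task2u	G1.03	1	0.15	0.83	0.67	57	0	0
task2u	G1.04	1	0.53	0.59	0.74	0	0	0
task2u	G1.05	1	0.15	0.25	0.58	26	25	0
task2u	G1.06	1	0.08	0.67	0.77	98	0	0
task2u	G1.07	1	0.44	0.56	0.54	25	0	0
task2u	G1.08	1	0.43	0.67	0.74	25	0	0
task2u	G1.09	1	0.63	0.37	0.59	0	25	0
task2u	G1.10	1	0.14	0.16	0.48	53	25	0
task3	G1.01	1	0.35	0.13	0.14	11	31	16
task3	G1.02	1	0.26	0.15	0.15	33	49	40
task3	G1.03	1	0.14	0.13	0.12	18	37	15
task3	G1.04	1	0.11	0.25	0.33	20	16	16
task3	G1.05	1	0.15	0.10	0.23	27	33	11
task3	G1.06	1	0.14	0.06	0.13	13	25	18
task3	G1.07	1	0.31	0.14	0.23	14	31	14
task3	G1.08	1	0.15	0.17	0.13	27	17	37
task3	G1.09	1	0.62	0.37	0.31	0	13	13
task3	G1.10	1	0.28	0.18	0.26	12	46	12
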