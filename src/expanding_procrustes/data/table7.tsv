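side	subject	group	uf_di	uh_di	fh_di	uf_pct	uh_pct	fh_pct
right	G1.01	1	0.20	0.27	0.13	0.0	25.0	45.0
right	G1.02	1	0.12	0.20	0.05	48.3	25.0	60.0
right	G1.03	1	0.11	0.21	0.13	43.3	23.3	76.7
right	G1.04	1	0.10	0.12	0.13	0.0	46.7	43.3
right	G1.05	1	0.33	0.26	0.09	20.0	25.0	0.0
right	G1.06	1	0.15	0.51	0.12	0.0	0.0	40.0
right	G1.07	1	0.13	0.14	0.56	0.0	30.0	0.0
right	G1.08	1	0.13	0.15	0.13	80.0	55.0	85.0
right	G1.09	1	0.17	0.21	0.19	20.0	30.0	25.0
right	G1.10	1	0.15	0.14	0.08	53.3	26.7	53.3
left	G1.01	1	0.18	0.23	0.14	24.4	0.0	26.7
left	G1.02	1	0.15	0.14	0.32	35.6	26.7	24.4
left	G1.03	1	0.28	0.18	0.13	0.0	25.5	0.0
left	G1.04	1	0.20	0.12	0.51	0.0	64.4	24.4
left	G1.05	1	0.31	0.15	0.14	24.4	57.8	60.0
left	G1.06	1	0.15	0.24	0.17	55.0	25.0	25.0
left	G1.07	1	0.24	0.31	0.42	0.0	25.7	25.7
left	G1.08	1	0.15	0.08	0.13	30.0	33.3	0.0
left	G1.09	1	0.39	0.37	0.15	0.0	25.0	60.0
left	G1.10	1	0.07	0.16	0.15	0.0	25.0	0.0
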