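side	subject	group	uf_di	uh_di	fh_di	uf_pct	uh_pct	fh_pct
right	G2.01	2	0.09	0.35	0.40	25.0	25.0	0.0
right	G2.02	2	0.13	0.31	0.15	0.0	0.0	37.5
right	G2.03	2	0.36	0.14	0.26	0.0	53.3	23.3
right	G2.04	2	0.13	0.36	0.12	37.5	27.5	95.0
right	G2.05	2	0.54	0.46	0.26	0.0	0.0	25.0
right	G2.06	2	0.19	0.14	0.15	20.0	26.0	62.0
right	G2.07	2	0.15	0.25	0.26	60.0	23.3	26.7
right	G2.08	2	0.15	0.89	0.24	0.0	0.0	0.0
right	G2.09	2	0.11	0.52	0.38	33.3	0.0	0.0
right	G2.10	2	0.07	0.14	0.12	53.3	26.7	43.3
left	G2.01	2	0.29	0.11	0.21	25.0	60.0	25.0
left	G2.02	2	0.61	0.26	0.48	0.0	24.6	13.8
left	G2.03	2	0.16	0.63	0.47	25.5	0.0	0.0
left	G2.04	2	0.65	0.15	0.33	23.3	60.0	0.0
left	G2.05	2	0.45	0.22	0.12	25.7	25.7	100.0
left	G2.06	2	0.08	0.14	0.11	47.5	35.0	55.0
left	G2.07	2	0.49	0.52	0.33	0.0	0.0	0.0
left	G2.08	2	0.23	0.42	0.29	21.7	24.4	26.8
left	G2.09	2	0.28	0.17	0.13	0.0	24.0	0.0
left	G2.10	2	0.17	0.19	0.21	0.0	25.5	25.5
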