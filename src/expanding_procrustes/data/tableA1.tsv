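subject	group	ru_max	rf_max	rh_max	lu_max	lf_max	lh_max
G1.01	1	50.0	113.2	128.8	70.7	167.8	156.5
G1.02	1	70.7	122.5	178.9	76.4	127.0	305.8
G1.03	1	90.0	150.2	219.8	81.4	130.6	258.4
G1.04	1	94.7	128.4	366.9	101.4	340.2	166.1
G1.05	1	152.8	191.9	204.0	159.5	232.4	210.7
G1.06	1	134.4	141.6	207.9	105.9	125.6	264.3
G1.07	1	98.9	216.4	219.0	112.2	170.4	253.5
G1.08	1	145.7	139.0	225.4	101.1	166.0	246.8
G1.09	1	232.2	319.8	924.7	353.8	306.9	689.6
G1.10	1	128.1	150.6	405.1	110.2	106.9	354.8
G2.01	2	352.8	239.0	158.7	239.4	210.9	141.5
G2.02	2	144.6	185.9	244.8	181.0	116.0	281.0
G2.03	2	80.6	161.4	208.3	73.7	138.2	313.7
G2.04	2	182.9	286.1	390.7	249.7	274.0	344.0
G2.05	2	92.4	189.4	211.6	102.3	185.6	182.8
G2.06	2	123.5	288.6	448.4	135.6	202.5	341.7
G2.07	2	169.4	237.1	312.6	122.1	164.6	412.0
G2.08	2	97.8	135.5	250.9	179.4	104.2	286.4
G2.09	2	94.4	264.5	203.2	66.0	108.9	225.2
G2.10	2	97.8	277.6	400.8	82.8	161.1	249.3
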