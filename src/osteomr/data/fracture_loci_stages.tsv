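locus	gene	snp_id	ea	eaf	or_disc	lo_disc	hi_disc	p_disc	or_repl	lo_repl	hi_repl	p_repl	or_comb	lo_comb	hi_comb	p_comb	n_cases	i2
2p16.2	SPTBN1	rs4233949	G	0.61	1.03	1.02	1.05	6.9e-5	1.04	1.05	1.05	8.9e-11	1.03	1.02	1.04	2.8e-14	185057	22.4
3p22.1	CTNNB1	rs430727	T	0.45	1.03	1.02	1.05	1.0e-4	1.03	1.02	1.04	1.1e-8	1.03	1.02	1.04	5.0e-12	185057	0
6q22.33	RSPO3	rs10457487	C	0.51	1.06	1.05	1.08	2.3e-15	1.04	1.03	1.05	1.7e-15	1.05	1.04	1.06	4.8e-28	185057	5
6q25.1	ESR1	rs2982570	C	0.58	1.05	1.04	1.07	8.1e-12	1.03	1.02	1.04	5.2e-10	1.04	1.03	1.05	4.5e-19	185057	23
7q31.31	WNT16_CPED1	rs2908007	A	0.60	1.08	1.06	1.10	1.2e-20	1.05	1.04	1.06	5.6e-22	1.06	1.05	1.07	2.3e-39	185055	0
7q21.3	C7orf76_SHFM1	rs6465508	G	0.34	1.05	1.03	1.07	4.0e-9	1.04	1.03	1.05	4.1e-12	1.04	1.03	1.05	2.0e-19	185056	35
7p14.1	STARD3NL	rs6959212	T	0.34	1.04	1.02	1.06	6.9e-6	1.02	1.01	1.04	1.1e-5	1.03	1.02	1.04	8.8e-10	185057	15.6
7p12.1	GRB10_COBL	rs1548607	G	0.32	1.05	1.03	1.07	3.2e-8	1.02	1.01	1.04	2.1e-4	1.03	1.02	1.05	4.7e-10	185052	40
9q34.11	FUBP3	rs7851693	G	0.35	1.03	1.01	1.06	1.3e-4	1.05	1.06	1.06	4.8e-16	1.04	1.03	1.05	5.0e-19	185057	23.5
10q21.1	MBL2_DKK1	rs11003047	G	0.11	1.09	1.07	1.12	6.2e-12	1.08	1.07	1.10	1.4e-21	1.09	1.07	1.10	9.5e-33	185057	0
11q13.2	LRP5	rs3736228	T	0.15	1.05	1.03	1.07	3.0e-5	1.07	1.05	1.08	2.8e-18	1.06	1.05	1.08	1.0e-21	185056	24.6
14q32.12	RPS6KA5	rs1286083	T	0.82	1.04	1.02	1.06	8.8e-5	1.05	1.04	1.07	3.0e-14	1.05	1.04	1.06	1.6e-17	185085	43.3
17q21.31	SOST_DUSP3_MEOX1	rs2741856	G	0.92	1.11	1.08	1.14	2.4e-12	1.08	1.06	1.11	5.3e-15	1.10	1.07	1.11	3.1e-25	184977	0
18p11.21	FAM210A_RNMT	rs4635400	A	0.36	1.06	1.04	1.07	1.5e-12	1.03	1.02	1.04	2.7e-9	1.04	1.03	1.05	1.1e-18	185057	22
21q22.2	ETS2	rs9980072	G	0.73	1.06	1.04	1.08	8.4e-12	1.03	1.01	1.04	1.8e-5	1.04	1.03	1.05	3.4e-13	185057	36
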