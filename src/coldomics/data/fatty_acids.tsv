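fatty_acid	ky_control_mean	ky_control_sd	ky_control_letter	ky_cold_mean	ky_cold_sd	ky_cold_letter	dn_control_mean	dn_control_sd	dn_control_letter	dn_cold_mean	dn_cold_sd	dn_cold_letter	rc_ky	rc_dn
FA 14:0	1.67	0.20	a	1.32	0.07	b	1.19	0.11	b	1.41	0.05	a	-20.73	18.69
FA 16:0	73.28	6.19	a	53.90	4.99	b	62.53	5.90	b	83.45	3.99	a	-26.45	33.46
FA 17:0	2.42	0.25	a	1.94	0.16	b	2.05	0.19	b	2.60	0.11	a	-19.77	27.24
FA 18:0	31.24	1.66	a	24.10	3.54	b	21.57	3.24	b	29.22	4.34	a	-22.85	35.45
FA 18:1	11.90	0.89	a	7.09	0.72	b	10.82	1.19	a	10.71	0.49	a	-40.42	-1.03
FA 18:2	28.20	5.40	a	15.65	0.69	b	19.41	2.34	a	20.01	1.00	a	-44.51	3.07
FA 18:3	209.34	30.49	a	137.83	5.04	b	105.54	6.86	a	106.51	5.67	a	-34.16	0.91
FA 19:1	0.27	0.03	a	0.24	0.01	a	0.23	0.02	b	0.29	0.01	a	-9.67	25.28
FA 20:0	4.05	0.56	a	3.95	0.15	a	3.34	0.18	b	4.45	0.27	a	-2.32	33.37
FA 20:1	0.46	0.04	a	0.35	0.03	b	0.39	0.01	b	0.43	0.02	a	-24.24	9.34
FA 20:2	0.37	0.02	a	0.31	0.04	a	0.36	0.02	b	0.45	0.01	a	-17.07	23.77
FA 22:0	2.90	0.18	a	2.78	0.22	a	2.84	0.15	b	3.94	0.06	a	-3.99	38.93
FA 22:1	0.07	0.001	a	0.05	0.01	b	0.07	0.01	a	0.07	0.03	a	-22.58	6.65
FA 22:2	0.01	0.001	a	0.01	0.001	a	0.01	0.001	a	0.02	0.002	a	-23.75	9.96
FA 23:0	2.05	0.13	a	2.01	0.16	a	1.84	0.07	b	2.51	0.10	a	-1.98	36.77
FA 24:0	9.62	0.74	a	8.93	0.97	ab	8.12	0.15	b	10.60	0.36	a	-7.17	30.63
TFA	377.85	21.73	a	260.47	9.87	b	240.30	19.19	b	276.66	2.19	a	-31.07	15.13
UFA	250.63	29.54	a	161.53	5.35	b	136.84	10.43	a	138.47	6.22	a	-35.55	1.19
SFA	127.22	8.71	a	98.94	8.56	b	103.46	8.75	b	138.19	8.21	a	-22.23	33.57
UFA/SFA	1.97	0.39	a	1.63	0.14	a	1.32	0.01	a	1.00	0.10	b	-17.26	-24.24
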