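lipid_class	ky_control_mean	ky_control_sd	ky_control_letter	ky_cold_mean	ky_cold_sd	ky_cold_letter	dn_control_mean	dn_control_sd	dn_control_letter	dn_cold_mean	dn_cold_sd	dn_cold_letter	rc_ky	rc_dn
MGDG	5084.35	236.46	b	6796.77	189.52	a	6328.62	534.29	a	5249.45	259.11	b	33.68	-17.05
DGDG	2256.06	252.23	b	2926.05	145.14	a	2623.10	252.67	a	2894.27	4.65	a	29.71	10.34
SQDG	1121.07	126.96	a	942.53	79.75	a	1191.25	14.00	a	1080.82	48.24	a	-15.93	-9.27
PA	69.44	8.18	a	52.95	5.79	a	52.89	1.11	a	61.25	5.99	a	-23.75	15.81
PC	309.01	29.72	b	448.79	32.48	a	364.89	35.20	a	319.34	17.01	a	45.23	-12.48
PE	469.40	35.85	b	591.79	34.20	a	487.52	29.78	a	444.07	24.58	a	26.07	-8.91
PG	1668.29	89.71	a	1777.14	17.50	a	1740.37	104.90	a	1685.85	47.56	b	6.52	-3.13
PI	626.04	21.41	b	729.07	22.99	a	440.92	41.57	b	528.48	66.77	a	16.46	19.86
PMeOH	18.92	1.06	a	18.36	0.98	a	21.99	0.68	a	21.00	1.59	a	-2.96	-4.50
LPE	14.97	1.09	b	18.64	1.64	a	26.03	2.58	b	41.83	3.00	a	24.52	60.70
LPC	17.24	1.39	a	16.38	1.19	a	23.05	2.42	a	23.80	0.36	a	-4.99	3.25
DG	856.76	29.89	b	1264.52	107.51	a	1080.69	92.26	b	1766.78	26.59	a	47.59	63.49
TG	171.88	4.30	a	88.54	6.00	b	87.91	7.84	b	133.00	2.28	a	-48.49	51.29
FA	377.86	21.73	a	260.47	9.89		240.32	19.19	b	276.68	2.19	a	-31.07	15.13
Total	13061.27	340.00	b	15932.01	357.56	a	14709.54	636.42	a	14526.62	249.47	a	21.98	-1.24
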