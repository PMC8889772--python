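lipid_class	ky_control_mean	ky_control_sd	ky_control_letter	ky_cold_mean	ky_cold_sd	ky_cold_letter	dn_control_mean	dn_control_sd	dn_control_letter	dn_cold_mean	dn_cold_sd	dn_cold_letter	rc_ky	rc_dn
MGDG	289.28	13.78	b	386.30	11.51	a	358.19	30.80	a	298.79	14.82	b	33.54	-16.58
DGDG	115.62	13.00	b	150.36	6.82	a	134.22	12.54	b	147.78	1.47	a	30.05	10.10
SQDG	49.32	5.57	a	41.18	3.19	a	49.10	1.09	a	45.80	1.44	b	-16.50	-6.72
PA	2.26	0.24	a	1.80	0.20	b	1.75	0.07	b	1.97	0.17	a	-20.35	12.57
PC	8.74	0.87	b	14.04	0.94	a	10.55	1.10	a	9.96	0.53	a	60.64	-5.59
PE	16.45	1.25	b	21.86	1.52	a	17.33	1.10	a	15.88	0.82	a	32.89	-8.37
PG	34.03	3.28	b	38.18	0.30	a	34.32	2.32	a	35.66	0.92	a	12.20	3.90
PI	5.45	1.00	a	5.66	0.65	a	3.85	0.41	a	4.20	0.33	a	3.85	9.09
PMeOH	0.55	0.02	a	0.55	0.03	a	0.65	0.02	a	0.64	0.04	a	0.00	-1.54
LPE	0.24	0.03	a	0.29	0.02	a	0.48	0.05	b	0.64	0.05	a	20.83	33.33
LPC	0.27	0.02	a	0.23	0.02	a	0.37	0.04	a	0.33	0.01	a	-14.81	-10.81
DG	35.67	0.81	b	58.63	5.45	a	48.16	4.44	b	84.13	2.05	a	64.37	74.69
TG	10.31	0.31	a	5.12	0.39	b	5.33	0.52	b	8.24	0.15	a	-50.34	54.60
FA	6.98	0.90	a	4.53	0.15	b	3.68	0.27	a	3.72	0.19	a	-35.10	1.09
Total	575.17	20.72	b	728.72	18.79	a	667.97	35.63	a	657.74	13.14	a	26.70	-1.53
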