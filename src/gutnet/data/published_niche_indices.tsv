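category	levins	shannon	occurrence
core	10.47	2.68	0.93
core	10.08	2.79	0.94
core	12.51	2.94	1.00
core	3.00	1.73	0.96
core_generalist	17.39	3.07	0.98
core_generalist	13.87	2.95	0.94
core_generalist	28.63	3.44	1.00
generalist	28.37	3.43	0.76
generalist	28.26	3.42	0.69
generalist	23.52	3.41	0.80
generalist	20.40	3.24	0.72
generalist	20.12	3.14	0.54
generalist	19.99	3.23	0.67
generalist	19.78	3.21	0.72
generalist	18.60	3.26	0.70
generalist	17.71	3.09	0.76
generalist	16.70	3.10	0.78
generalist	14.78	3.07	0.74
generalist	14.69	3.07	0.70
generalist	14.55	3.06	0.81
generalist	13.89	3.00	0.72
generalist	13.38	3.00	0.72
specialist	1.60	0.56	0.04
specialist	1.60	0.56	0.04
specialist	1.59	0.68	0.06
specialist	1.51	0.62	0.06
specialist	1.47	0.50	0.04
specialist	1.17	0.27	0.04
specialist	1.04	0.11	0.06
specialist	1.02	0.06	0.04
specialist	1.02	0.05	0.04
specialist	1.92	0.67	0.04
specialist	1.81	0.69	0.04
specialist	1.80	0.64	0.04
unique	7.68	2.23	0.37
unique	7.91	2.27	0.28
unique	9.43	2.43	0.33
unique	9.25	2.37	0.28
unique	10.81	2.57	0.31
unique	6.55	2.27	0.37
unique	11.45	2.64	0.37
unique	6.81	2.16	0.30
unique	3.59	1.69	0.30
unique	5.28	2.11	0.33
unique	5.82	2.00	0.28
unique	7.55	2.35	0.31
unique	8.81	2.42	0.30
unique	14.38	2.88	0.46
unique	6.47	2.21	0.43
unique	7.49	2.62	0.67
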