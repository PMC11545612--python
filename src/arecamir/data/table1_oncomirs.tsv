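mirna	tn_fr	p	oec_fc	sas_fc	avg_fc
miR-513a-5p	4.28	1.90e-3	39.40	26.15	32.77
miR-483-3p	1.80	8.71e-4	1.94	54.03	27.99
miR-615-3p	7.56	9.83e-24	1.19	29.95	15.57
miR-636	1.58	4.40e-4	8.35	3.54	5.95
miR-589-3p	2.59	5.05e-14	10.19	1.39	5.79
miR-135b-5p	2.46	1.31e-7	3.41	5.82	4.62
miR-508-3p	2.72	2.85e-2	4.88	4.11	4.49
miR-518c-5p	2.98	2.03e-2	3.36	3.96	3.66
miR-9-5p	10.26	3.01e-14	2.91	3.30	3.10
miR-663a	2.80	8.42e-6	1.43	3.87	2.65
miR-129-5p	1.94	1.04e-2	3.32	1.73	2.53
miR-454-5p	2.00	6.92e-11	1.53	3.35	2.44
miR-506-3p	5.41	7.73e-3	2.21	2.02	2.11
miR-509-3p	3.76	4.58e-3	2.58	1.59	2.08
miR-181a-5p	1.46	3.75e-9	1.21	2.91	2.06
miR-767-3p	8.32	1.26e-20	2.62	1.00	1.81
miR-324-3p	1.66	5.75e-12	2.20	1.26	1.73
miR-576-5p	1.61	1.14e-7	2.46	1.00	1.73
miR-33b-5p	1.55	4.37e-3	2.23	1.00	1.62
miR-105-5p	48.05	1.52e-16	2.14	1.00	1.57
miR-501-5p	1.53	4.17e-4	2.15	0.91	1.53
miR-142-3p	1.69	6.95e-5	1.95	1.10	1.53
miR-33a-5p	1.70	5.59e-4	0.87	2.13	1.50
miR-342-3p	1.47	4.75e-3	2.07	0.93	1.50
miR-629-3p	2.18	7.85e-16	1.20	1.72	1.46
miR-20b-5p	2.67	1.04e-2	1.47	1.31	1.39
miR-222-3p	1.86	8.44e-17	1.68	0.92	1.30
miR-551a	1.55	1.03e-2	1.00	1.55	1.28
miR-191-5p	1.38	7.19e-5	1.60	0.90	1.25
miR-301a-3p	3.75	4.28e-27	1.11	1.33	1.22
miR-590-5p	1.44	3.50e-6	0.98	1.42	1.20
miR-424-5p	2.62	4.37e-13	1.11	1.28	1.19
miR-181a-3p	1.24	5.97e-3	1.14	1.21	1.18
miR-20a-5p	1.70	3.39e-5	1.24	1.09	1.16
miR-455-5p	2.25	5.93e-21	1.23	1.04	1.14
miR-767-5p	39.86	7.03e-19	1.26	1.00	1.13
miR-196b-5p	12.84	4.35e-36	0.96	1.30	1.13
miR-19a-3p	2.16	4.85e-9	1.04	1.21	1.12
miR-141-3p	1.40	1.42e-3	0.86	1.37	1.11
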