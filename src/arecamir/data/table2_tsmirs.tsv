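mirna	tn_fr	p	oec_fc	sas_fc	avg_fc
miR-499a-5p	-7.97	5.04e-4	-5.68	-4.08	-4.75
miR-190a-5p	-2.83	2.83e-8	-2.75	-16.09	-4.69
miR-1-3p	-11.77	3.44e-4	-5.12	-4.25	-4.64
miR-154-5p	-2.52	1.61e-6	-9.82	-1.96	-3.26
miR-410-3p	-4.36	4.31e-4	-3.37	-2.18	-2.65
miR-329-3p	-1.87	4.52e-4	-2.43	-2.76	-2.59
miR-376b-3p	-1.63	1.29e-2	-4.45	-1.69	-2.45
miR-378a-5p	-3.96	7.84e-5	-1.48	-7.02	-2.44
miR-376c-3p	-4.48	7.18e-4	-3.43	-1.86	-2.41
miR-758-3p	-1.36	2.13e-3	-6.19	-1.36	-2.23
miR-432-5p	-2.47	2.09e-5	-1.18	-7.20	-2.03
miR-409-3p	-1.34	1.15e-3	-1.71	-2.18	-1.92
miR-382-5p	-1.62	6.75e-4	-2.33	-1.63	-1.92
miR-199b-5p	-2.39	3.64e-8	-3.52	-1.29	-1.88
miR-379-5p	-4.05	7.97e-5	-3.13	-1.30	-1.84
miR-377-3p	-1.99	3.27e-4	-2.75	-1.34	-1.80
miR-495-3p	-3.69	4.36e-4	-2.53	-1.31	-1.73
let-7b-5p	-1.43	1.27e-6	-1.30	-1.97	-1.57
miR-369-3p	-2.89	5.21e-5	-3.39	-1.00	-1.54
miR-548b-3p	-1.69	3.11e-2	-2.91	-1.00	-1.49
miR-337-3p	-3.86	3.99e-4	-1.00	-2.87	-1.48
miR-485-5p	-1.44	3.54e-2	-2.80	-1.00	-1.47
miR-376a-3p	-2.71	5.16e-3	-3.68	-0.88	-1.43
miR-23b-3p	-1.61	1.90e-9	-1.40	-1.43	-1.41
miR-206	-4.94	8.71e-4	-2.31	-0.99	-1.38
miR-128-3p	-1.74	4.36e-3	-1.02	-1.78	-1.30
miR-27b-3p	-1.95	1.15e-9	-1.32	-1.25	-1.28
miR-299-3p	-2.08	4.51e-3	-1.75	-1.00	-1.27
miR-491-5p	-1.93	4.62e-4	-0.98	-1.79	-1.27
miR-369-5p	-3.35	2.58e-6	-1.72	-1.00	-1.26
miR-655-3p	-3.06	1.59e-3	-1.61	-1.00	-1.24
miR-215-5p	-1.82	4.93e-6	-1.67	-0.97	-1.23
miR-140-5p	-1.62	5.66e-8	-1.32	-1.14	-1.22
miR-199a-5p	-1.32	1.82e-2	-1.49	-1.00	-1.20
miR-107	-1.24	2.25e-3	-1.13	-1.27	-1.20
miR-30e-3p	-2.29	2.42e-11	-1.31	-1.08	-1.19
miR-152-3p	-1.50	2.91e-6	-1.05	-1.26	-1.14
miR-30a-5p	-3.85	1.76e-9	-1.42	-0.93	-1.12
miR-30a-3p	-5.55	1.15e-8	-1.42	-0.92	-1.12
miR-100-5p	-3.72	1.02e-16	-0.91	-1.45	-1.12
miR-181c-5p	-1.28	8.72e-4	-1.42	-0.91	-1.11
miR-29a-3p	-2.85	4.19e-14	-1.00	-1.24	-1.11
let-7f-5p	-1.52	7.75e-6	-1.22	-0.94	-1.07
miR-30e-5p	-2.45	5.16e-11	-1.34	-0.85	-1.04
miR-532-5p	-1.20	3.58e-3	-0.87	-1.28	-1.04
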