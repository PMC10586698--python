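cohort_id	patient_id	mean_score	hpd_lower	hpd_upper	status
C1	C1-P1	0.11	0.089	0.31	N
C1	C1-P2	0.44	0.29	0.67	Y
C1	C1-P3	-0.069	-0.24	0.11	N
C1	C1-P4	-0.96	-1.54	-0.37	N
C1	C1-P5	-0.17			N
C2	C2-P1	1			Y
C2	C2-P2	1.37	1.34	1.40	Y
C2	C2-P3	0.48	0.43	0.52	Y
C2	C2-P4	1.51	1.46	1.55	Y
C2	C2-P5	0.44	0.38	0.48	Y
C2	C2-P6	0.54	0.49	0.57	Y
C2	C2-P7	0.50	0.46	0.54	Y
C2	C2-P8	1.55	1.51	1.60	Y
C3	C3-P1	-1.18	-1.19	-1.17	N
C3	C3-P2	-1.26	-1.26	-1.24	N
C3	C3-P3	-1.74	-1.75	-1.73	N
C3	C3-P4	-2.32	-2.33	-2.306	N
C3	C3-P5	-1.55	-1.55	-1.539	N
C3	C3-P6	-1.20	-1.20	-1.186	N
C3	C3-P7	-1.45	-1.46	-1.44	N
C3	C3-P8	-2.13	-2.14	-2.127	N
C3	C3-P9	-1.58	-1.587	-1.572	N
C3	C3-P10	-1.30	-1.31	-1.299	N
C3	C3-P11	-1.18	-1.19	-1.177	N
C3	C3-P12	-1.43			N
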