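# Pseudo signature: the 43 candidate genes most correlated with metastasis
# risk (every stability is 1.0000), used as the comparison control.
gene_id	gene_name	cox_beta	cox_p	stability
28	ABO	-0.77	7.50E-4	1.0000
86	ACTL6A	0.69	1.50E-3	1.0000
960	CD44	-0.54	2.30E-3	1.0000
1917	EEF1A2	0.20	3.60E-3	1.0000
3537	IGLC1	-0.28	1.00E-3	1.0000
6810	STX4	-0.78	3.90E-3	1.0000
6921	TCEB1	0.95	4.00E-4	1.0000
9541	CIR	-0.89	1.40E-3	1.0000
9648	GCC2	-0.25	3.30E-3	1.0000
9675	KIAA0406	0.63	2.80E-4	1.0000
9764	KIAA0513	0.53	3.70E-3	1.0000
9837	GINS1	0.41	1.10E-3	1.0000
10051	SMC4	0.71	2.00E-3	1.0000
10057	ABCC5	0.57	4.20E-4	1.0000
10628	TXNIP	-0.50	1.10E-3	1.0000
10961	ERP29	-0.77	2.50E-3	1.0000
23167	EFR3A	0.69	1.60E-3	1.0000
23174	ZCCHC14	0.87	1.40E-3	1.0000
25793	FBXO7	-1.08	2.60E-3	1.0000
27250	PDCD4	-0.46	2.00E-3	1.0000
27350	APOBEC3C	-0.54	4.70E-3	1.0000
28813	IGLV2-23	-0.23	1.00E-3	1.0000
28814	IGLV2-18	-0.33	1.10E-3	1.0000
28816	IGLV2-11	-0.24	8.90E-4	1.0000
29035	C16orf72	-0.39	1.40E-3	1.0000
29127	RACGAP1	0.65	1.30E-4	1.0000
50802	IGK	-0.24	3.30E-3	1.0000
51110	LACTB2	0.57	8.60E-4	1.0000
51222	ZNF219	-0.68	9.80E-4	1.0000
54732	TMED9	0.59	1.50E-3	1.0000
55110	FLJ10292	0.35	1.80E-3	1.0000
55508	SLC35E3	0.41	1.60E-3	1.0000
55596	ZCCHC8	1.00	7.60E-4	1.0000
57092	PCNP	0.91	2.00E-3	1.0000
58189	WFDC1	0.44	3.10E-4	1.0000
79822	ARHGAP28	-0.45	7.30E-4	1.0000
80700	UBXD1	-0.68	1.90E-3	1.0000
118433	RPL23AP7	0.47	4.90E-3	1.0000
259266	ASPM	0.34	3.80E-3	1.0000
442334	ARF1P1	0.35	1.80E-3	1.0000
650405	LOC650405	-0.34	5.10E-4	1.0000
652493	LOC652493	-0.26	1.50E-3	1.0000
652694	LOC652694	-0.32	2.70E-3	1.0000
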