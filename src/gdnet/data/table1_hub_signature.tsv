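# Hub-based signature: 43 candidate genes that are also network hubs.
# cox_beta / cox_p are averages over the 400 resampling runs; stability is
# the fraction of runs with Cox p < 0.05.
gene_id	gene_name	cox_beta	cox_p	stability
701	BUB1B	0.46	1.07E-2	0.9625
718	C3	-0.27	1.43E-2	0.9300
890	CCNA2	0.39	8.70E-3	0.9850
891	CCNB1	0.40	1.95E-2	0.9025
960	CD44	-0.54	2.30E-3	1.0000
1917	EEF1A2	0.20	3.60E-3	1.0000
2146	EZH2	0.33	1.06E-2	0.9675
3091	HIF1A	0.44	1.94E-2	0.9150
3105	HLA-A	-0.51	1.73E-2	0.9200
3106	HLA-B	-0.39	1.06E-2	0.9600
3107	HLA-C	-0.75	2.70E-3	0.9975
3493	IGHA1	-0.39	9.72E-3	0.9675
3507	IGHM	-0.34	9.60E-3	0.9750
3659	IRF1	-0.51	1.61E-3	0.9300
3838	KPNA2	0.47	8.90E-3	0.9700
4591	TRIM37	0.58	3.90E-3	0.9950
4751	NEK2	0.38	1.80E-2	0.9200
4790	NFKB1	-0.68	6.70E-3	0.9875
4798	NFRKB	-0.78	1.53E-2	0.9300
5241	PGR	-0.13	1.64E-2	0.9300
5501	PPP1CC	1.06	8.10E-3	0.9700
5688	PSMA7	0.59	7.30E-3	0.9700
5708	PSMD2	0.67	1.97E-2	0.9100
5998	RGS3	0.66	1.02E-2	0.9650
6241	RRM2	0.37	3.80E-3	0.9975
6626	SNRPA	-0.64	1.49E-2	0.9525
6790	AURKA	0.53	2.60E-3	0.9975
6921	TCEB1	0.95	4.00E-4	1.0000
7133	TNFRSF1B	-0.41	1.37E-2	0.9525
7138	TNNT1	0.13	1.60E-2	0.9275
7289	TULP3	0.55	1.64E-2	0.9275
7936	RDBP	0.74	3.90E-3	0.9900
8445	DYRK2	0.75	2.10E-3	0.9975
8668	EIF3I	-0.70	2.01E-2	0.9025
9021	SOCS3	-0.47	1.16E-2	0.9600
9459	ARHGEF6	-0.52	3.30E-3	0.9975
10051	SMC4	0.71	2.00E-3	1.0000
10521	DDX17	-0.34	1.44E-2	0.9525
11065	UBE2C	0.43	8.70E-3	0.9650
11260	XPOT	0.65	8.90E-3	0.9725
11335	CBX3	0.85	4.30E-3	0.9925
55257	C20orf20	0.67	1.92E-2	0.9025
57122	NUP107	0.60	1.42E-2	0.9300
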