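# Per-cohort discrimination of the pseudo signature: hazard ratio with 95% CI
# and two-group log-rank p-value. GSE2034 is the training cohort; the other
# six rows are the independent test cohorts.
dataset	HR	HR_CI_low	HR_CI_high	logrank_p	role
GSE2034	4.65	2.95	7.33	3.14E-13	training
GSE1456	1.90	1.00	3.60	3.20E-02	independent
GSE3493	2.05	1.18	3.59	5.56E-03	independent
GSE4922	1.72	1.11	2.66	9.60E-03	independent
GSE7390	1.76	1.06	2.93	5.40E-02	independent
GSE11121	2.02	1.11	3.67	1.30E-02	independent
GSE12093	3.84	1.37	10.73	2.90E-03	independent
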