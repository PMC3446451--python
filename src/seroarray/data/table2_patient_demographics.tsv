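patient_id	subtype	sex	age_years	wbc	esr_mm_hr	crp_mg_l	rf	ana_titer
O1	oligo	Male	6.6	8.2	10.0	15.0	Negative	1:80
O2	oligo	Female	2.5	12.8	37.0	26.0	Negative	1:80
O3	oligo	Male	8.5	6.6	2.0	6.4	Negative	Negative
E1	extended_oligo	Female	7.5	9.5	22.0	9.0	Negative	1:80
E2	extended_oligo	Female	4.7	10.9	10.0	8.4	Negative	Negative
E3	extended_oligo	Female	11.0	9.1	62.0	66.5	Negative	Negative
P1	poly	Female	3.2	11.0	31.0	4.0	Negative	Negative
P2	poly	Female	16.6	11.8	110.0	72.0	231.0	Negative
P3	poly	Female	2.2	7.5	10.0	8.6	Negative	Negative
P4	poly	Female	2.6	10.1	45.0	19.1	Negative	1:320
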