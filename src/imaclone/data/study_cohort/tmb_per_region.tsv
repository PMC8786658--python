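patient_id	region_label	tmb
P01	RUL	1.13
P01	RML	0.92
P01	RLL	0.74
P01	LUL	1.04
P01	LLL	1.28
P03	RLL1	0.86
P03	RLL2	0.89
P03	RLL3	1.01
P04	RLL	0.77
P04	RUL1	1.10
P04	RUL2	1.48
P05	RLL1	1.39
P05	RLL2	1.63
P05	RLL3	1.34
P06	RUL	1.04
P06	RML	0.89
P06	LUL	1.13
P06	LN	1.25
P07	LLL	0.74
P07	RLL	0.33
P08	LLL1	0.56
P08	LLL2	0.86
P08	LLL3	0.80
P08	LLL4	0.98
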