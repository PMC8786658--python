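patient_id	region_a	region_b	jaccard
P01	RUL	RML	0.52
P01	RUL	RLL	0.01
P01	RUL	LUL	0.60
P01	RUL	LLL	0.53
P01	RML	RLL	0.01
P01	RML	LUL	0.55
P01	RML	LLL	0.49
P01	RLL	LUL	0.01
P01	RLL	LLL	0.01
P01	LUL	LLL	0.58
P03	RLL1	RLL2	0.52
P03	RLL1	RLL3	0.59
P03	RLL2	RLL3	0.48
P04	RLL	RUL1	0.26
P04	RLL	RUL2	0.21
P04	RUL1	RUL2	0.38
P05	RLL1	RLL2	0.29
P05	RLL1	RLL3	0.30
P05	RLL2	RLL3	0.27
P06	RUL	RML	0.35
P06	RUL	LUL	0.27
P06	RUL	LN	0.34
P06	RML	LUL	0.26
P06	RML	LN	0.32
P06	LUL	LN	0.23
P07	LLL	RLL	0.01
P08	LLL1	LLL2	0.20
P08	LLL1	LLL3	0.19
P08	LLL1	LLL4	0.16
P08	LLL2	LLL3	0.31
P08	LLL2	LLL4	0.47
P08	LLL3	LLL4	0.28
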