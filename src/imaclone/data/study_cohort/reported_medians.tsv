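patient_id	reported_median
P01	0.50
P03	0.52
P04	0.26
P05	0.29
P06	0.30
P07	0.01
P08	0.24
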