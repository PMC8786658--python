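patient_id	n_branch_private	n_truncal	reported_percent
P01	37	37	50
P03	30	31	49.1
P04	112	24	82.3
P05	68	36	65.4
P06	78	25	75.7
P07	42	0	NA
P08	41	17	70.7
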