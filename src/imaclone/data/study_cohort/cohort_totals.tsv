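key	value
n_somatic_variants	4059
n_regions	24
n_patients	7
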