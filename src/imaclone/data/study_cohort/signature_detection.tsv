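signature	n_samples	n_total
1	23	24
2_13	6	24
6	5	24
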