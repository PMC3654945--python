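d	median_interhalf_pct_identity
0.2	65.57
0.4	46.90
0.6	32.89
0.8	24.78
1.0	20.27
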