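time_s,front_m
20,0.02
40,0.03
60,0.04
180,0.05
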