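glucose_mM,sr_percent
5,19.4
10,22.9
20,26.3
30,28.7
40,30.6
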