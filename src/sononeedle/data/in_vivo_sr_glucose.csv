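glucose_mM,sr_percent
5.2,7.6
9.9,11.7
10.2,13.2
12.8,11.5
15.4,16.2
17.6,16.9
20.0,20.4
21.8,18.1
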