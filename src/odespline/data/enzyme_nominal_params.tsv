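parameter	value
k1	0.18
k2	0.2
k3	0.23
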