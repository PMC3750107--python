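parameter	value
k1	1.0
k2	1.6
k3	0.05
k16	0.4
k34	0.04
k43	0.01
k61	0.3
k67	0.7
k76	0.1
k23	0.3
k25	0.9
k28	0.06
k89	0.07
k98	0.01
a	0.04
J11	0.5
J12	5.0
J15	0.001
J18	0.6
J61	5.0
J62	8.0
J65	6.0
J68	7.0
J13	0.002
J63	2.0
Km1	0.5
Km2	4.0
Km4	0.3
Km9	0.005
kp	0.05
phi1	0.005
phi2	0.1
phi3	0.023
phi4	0.03
phi5	0.01
phi6	0.06
phi7	0.04
phi8	0.06
phi9	0.05
Fm	0.005
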