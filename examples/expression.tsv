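gene	ctrl_w0	ctrl_w8	skov3_sorafenib_w16
PLCG1	95	105	1000
PRKCA	200	210	780
ITPR1	150	160	300
HRAS	120	130	340
RAF1	90	110	185
NF1	250	240	95
NOTCH1	100	100	105
HES1	180	175	190
CCND1	140	150	138
CDK4	160	170	162
RB1	130	120	128
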