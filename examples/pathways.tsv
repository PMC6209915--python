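pathway	gene	arr
PLC_SIGNALING	PLCG1	1
PLC_SIGNALING	PRKCA	1
PLC_SIGNALING	ITPR1	0.5
RAS_MAPK	HRAS	1
RAS_MAPK	RAF1	1
RAS_MAPK	NF1	-1
RAS_MAPK	PLCG1	0.5
NOTCH_SIGNALING	NOTCH1	1
NOTCH_SIGNALING	HES1	1
CELL_CYCLE	CCND1	1
CELL_CYCLE	CDK4	1
CELL_CYCLE	RB1	-1
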