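sample	cell_line	drug	timepoint_weeks	is_control
ctrl_w0	SKOV-3	none	0	1
ctrl_w8	SKOV-3	none	8	1
skov3_sorafenib_w16	SKOV-3	Sorafenib	16	0
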