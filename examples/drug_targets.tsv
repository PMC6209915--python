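drug	targets
U73122	PLC
Sapitinib	EGFR,ERBB2,ERBB3
Afuresertib	AKT1,AKT2,AKT3
FLI-06	NOTCH1
Sorafenib	RAF1,BRAF,KDR
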