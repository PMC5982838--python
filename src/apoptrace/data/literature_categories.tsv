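# family -> functional category
family	category
ENDOG	DNase
ZEN1	DNase
NUC1	DNase
AIFM1	AIF
AIFM2	AIF
AIFM3	AIF
NDI1	AIF
Caspase	Protease
Metacaspase	Protease
OMI_fungal	Protease
OMI_animal	Protease
BIR	Inhibitor
API5	Inhibitor
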