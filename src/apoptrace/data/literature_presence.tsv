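# Presence/absence of apoptotic protein families across lineage groups,
# curated from published reports of homologs (see literature_evidence.tsv
# for the per-cell supporting observations). 1 = at least one homolog
# reported in the group's organisms within the family's branch.
family	Opisthokonta	Amoebozoa	SAR	Excavata	Archaeplastida	Eubacteria	Archaea	Virus
ENDOG	1	0	1	1	1	1	0	0
ZEN1	1	0	1	0	1	1	0	0
NUC1	1	1	1	1	0	1	0	1
AIFM1	1	1	0	1	0	1	0	0
AIFM2	1	1	1	1	1	1	0	0
AIFM3	1	0	0	0	0	1	0	0
NDI1	1	1	1	1	1	1	0	0
Caspase	1	0	1	0	0	0	0	1
Metacaspase	1	0	0	0	1	1	0	0
OMI_fungal	1	0	0	0	1	1	0	0
OMI_animal	1	1	1	0	1	1	0	0
BIR	1	0	1	1	1	0	0	1
API5	1	0	0	0	0	0	0	0
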