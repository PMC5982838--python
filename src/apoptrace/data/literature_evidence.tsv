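# Supporting observation behind each presence cell of
# literature_presence.tsv (organism-level evidence reported in the
# apoptosis literature). Cells not listed here are absences, either
# reported explicitly (noted below) or lacking any reported homolog.
family	group	evidence
ENDOG	Opisthokonta	apoptotic function shown in yeast and animals
ENDOG	Excavata	apoptotic function shown in trypanosomes
ENDOG	SAR	homologs in Toxoplasma and Reticulomyxa
ENDOG	Archaeplastida	homologs in Volvox and Chlamydomonas
ENDOG	Eubacteria	family branch contains eubacterial (but not archaeal) proteins; mitochondrial localization
ZEN1	Archaeplastida	apoptotic function described in plants
ZEN1	Opisthokonta	fungal homologs (e.g. Moniliophthora) in the plant ZEN1 branch
ZEN1	SAR	apicomplexan homologs (e.g. Plasmodium) in the plant ZEN1 branch
ZEN1	Eubacteria	eubacterial homologs in the plant ZEN1 branch
NUC1	Opisthokonta	animal apoptotic DNase; yeast NUC1
NUC1	SAR	homologs in ciliates and Reticulomyxa
NUC1	Excavata	homolog in Trichomonas
NUC1	Amoebozoa	homolog in Dictyostelium
NUC1	Eubacteria	DNase II domain present in eubacterial proteins (absent from archaea)
NUC1	Virus	DNase II domain present in viral proteins
AIFM1	Opisthokonta	metazoan AIFM1 sequences in the AIFM1 sub-branch
AIFM1	Amoebozoa	Dictyostelium sequences in the AIFM1 sub-branch
AIFM1	Excavata	Naegleria sequences in the AIFM1 sub-branch
AIFM1	Eubacteria	eubacterial AIFM1 proteins sharing the AIF_C domain architecture
AIFM2	Opisthokonta	branch contains proteins from all five ancient eukaryotic groups
AIFM2	Amoebozoa	branch contains proteins from all five ancient eukaryotic groups
AIFM2	SAR	branch contains proteins from all five ancient eukaryotic groups
AIFM2	Excavata	branch contains proteins from all five ancient eukaryotic groups
AIFM2	Archaeplastida	branch contains proteins from all five ancient eukaryotic groups
AIFM2	Eubacteria	branch contains eubacterial proteins
AIFM3	Opisthokonta	human AIM3 oxidoreductase with Rieske domain
AIFM3	Eubacteria	AIFM1/AIFM3 branch contains both eukaryotic and bacterial proteins
NDI1	Opisthokonta	branch contains sequences from all five ancient eukaryotic groups (incl. yeast NDI1)
NDI1	Amoebozoa	branch contains sequences from all five ancient eukaryotic groups
NDI1	SAR	branch contains sequences from all five ancient eukaryotic groups
NDI1	Excavata	branch contains sequences from all five ancient eukaryotic groups
NDI1	Archaeplastida	branch contains sequences from all five ancient eukaryotic groups
NDI1	Eubacteria	branch contains eubacterial proteins
Caspase	Opisthokonta	animal caspases
Caspase	SAR	caspase-like proteases of Reticulomyxa in the animal caspase branch
Caspase	Virus	viral peptidases closely related to the animal caspase branch (hijacked from hosts)
Metacaspase	Opisthokonta	fungal metacaspases (e.g. yeast MCA1)
Metacaspase	Archaeplastida	plant metacaspases
Metacaspase	Eubacteria	bacterial members of the shared peptidase C14 tree
OMI_fungal	Opisthokonta	yeast OMI/HTRA (NMA111)
OMI_fungal	Archaeplastida	putative chloroplast proteases of Arabidopsis and Chlamydomonas in the fungal-type branch
OMI_fungal	Eubacteria	bacterial proteins more closely related to yeast OMI than to human HTRA
OMI_animal	Opisthokonta	human OMI/HTRA proteins (and TYSND1 in the enclosing branch)
OMI_animal	Archaeplastida	putative Arabidopsis protease in the animal-type branch
OMI_animal	SAR	Paramecium proteases in the enclosing branch
OMI_animal	Amoebozoa	Dictyostelium proteases in the enclosing branch
OMI_animal	Eubacteria	putative bacterial serine proteases united with the human branch
BIR	Opisthokonta	survivin/IAP-family BIR-domain proteins of animals and fungi
BIR	Excavata	Naegleria gruberi protein D2UXF5
BIR	SAR	Paramecium tetraurelia protein A0CYG7
BIR	Archaeplastida	Guillardia theta protein L1JDG1
BIR	Virus	viral BIR-domain proteins
API5	Opisthokonta	human AAC11 apoptosis inhibitor
# API5 is reported absent from eubacteria, archaea and viruses; homologs in
# additional eukaryotic groups are reported but the groups are not named,
# so those cells are conservatively left 0 here.
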