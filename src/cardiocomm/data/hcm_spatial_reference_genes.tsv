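gene	affected_cell_group	direction	established_hcm_gene
ABCA10	Cardiomyocyte;Fibroblast	Decreased	no
ABCA6	Cardiomyocyte	Decreased	no
ABCA8	Cardiomyocyte	Decreased	no
AC010680.1	Cardiomyocyte	Increased	no
AC010680.5	Cardiomyocyte	Increased	no
ADH1B	Cardiomyocyte	Decreased	no
AGT	Endothelial;Pericyte	Decreased	no
C1R	Fibroblast	Decreased	no
C1S	Fibroblast	Decreased	no
CCL21	Endothelial	Decreased	no
CD74	Dendritic	Decreased	no
COL1A2	Neuronal	Decreased	no
CPE	Pericyte	Decreased	no
EMC10	Cardiomyocyte	Decreased	no
FABP4	Endothelial;Pericyte	Decreased	no
FBLN2	Fibroblast	Decreased	no
HES1	Fibroblast	Decreased	no
HES4	Smooth Muscle	Decreased	no
HLA-DRA	Dendritic	Decreased	no
HLA-DRB1	Dendritic	Decreased	no
IGFBP5	Endothelial	Decreased	no
MEG3	Cardiomyocyte;Fibroblast	Decreased	no
MMRN1	Endothelial	Decreased	no
MS4A6A	Dendritic	Decreased	no
MYH7B	Cardiomyocyte	Decreased	no
MYL2	Cardiomyocyte	Increased	yes
NDUFA4L2	Pericyte	Decreased	no
NEBL	Cardiomyocyte	Increased	no
NPPB	Cardiomyocyte	Decreased	no
PDGFRB	Pericyte;Smooth Muscle	Decreased	no
PLA2G2A	Cardiomyocyte	Decreased	no
PTGIR	Cardiomyocyte	Decreased	no
RP11-394O4.5	Smooth Muscle	Decreased	no
RP11-532N4.2	Cardiomyocyte	Decreased	no
SAT1	Dendritic	Decreased	no
SLC8A1	Cardiomyocyte	Decreased	no
SORBS2	Cardiomyocyte	Decreased	no
SPARC	Neuronal	Decreased	no
SPP1	Neuronal	Decreased	no
TFPI	Endothelial	Decreased	no
TMSB4X	Endothelial	Decreased	no
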