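gene	side	pathways	gwas	linkage	cnv	methylation	diff_expression	exome	brain_expression
CACNA1C	A	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;serotonergic_synapse	1	0	0	1	0	1	high
GNAS	A	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;serotonergic_synapse	0	0	0	1	0	1	high
GRIA1	A	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;neuroactive_ligand_receptor	0	1	0	0	0	0	high
GRIA3	A	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;neuroactive_ligand_receptor	0	0	0	0	0	1	high
DRD2	A	dopaminergic_synapse;neuroactive_ligand_receptor;camp_signaling	1	1	0	0	0	0	low
GNAO1	A	glutamatergic_synapse;dopaminergic_synapse;serotonergic_synapse	0	0	0	0	0	1	high
MAPK3	A	glutamatergic_synapse;camp_signaling;serotonergic_synapse	0	0	1	0	0	0	high
PLCB1	A	glutamatergic_synapse;dopaminergic_synapse;serotonergic_synapse	0	0	0	1	0	0	high
PRKCA	A	glutamatergic_synapse;dopaminergic_synapse;serotonergic_synapse	0	0	0	1	0	0	high
AKT1	A	dopaminergic_synapse;camp_signaling	0	1	0	0	0	1	high
CACNA1B	A	dopaminergic_synapse;serotonergic_synapse	0	0	0	0	0	1	high
CALM1	A	dopaminergic_synapse;camp_signaling	0	0	0	1	0	0	high
CAMK2A	A	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
CAMK2B	A	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
DRD3	A	dopaminergic_synapse;neuroactive_ligand_receptor	0	1	0	0	0	1	low
GRIK5	A	glutamatergic_synapse;neuroactive_ligand_receptor	0	0	0	0	0	1	high
MAPK8	A	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
PLA2G4A	A	glutamatergic_synapse;serotonergic_synapse	0	1	0	0	0	0	low
PPP3CC	A	glutamatergic_synapse;dopaminergic_synapse	0	1	0	0	0	0	high
PTGER3	A	neuroactive_ligand_receptor;camp_signaling	0	0	0	0	0	1	low
SLC18A1	A	dopaminergic_synapse;serotonergic_synapse	0	1	0	0	0	0	low
VIPR2	A	neuroactive_ligand_receptor;camp_signaling	0	0	1	0	0	0	low
CAMK2G	B	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;neuroactive_ligand_receptor	0	0	0	1	1	0	high
MYC	B	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;serotonergic_synapse	0	0	0	1	0	0	high
SDCBP	B	glutamatergic_synapse;dopaminergic_synapse;camp_signaling;neuroactive_ligand_receptor	0	0	0	0	0	1	high
ARNT	B	dopaminergic_synapse;camp_signaling;serotonergic_synapse	0	1	0	0	0	0	high
EPB41L1	B	dopaminergic_synapse;neuroactive_ligand_receptor;camp_signaling	0	0	0	0	0	1	high
ERBB2	B	dopaminergic_synapse;neuroactive_ligand_receptor;camp_signaling	0	0	0	0	0	1	high
FSCN1	B	glutamatergic_synapse;dopaminergic_synapse;serotonergic_synapse	0	0	0	1	1	1	high
SLC9A3R1	B	glutamatergic_synapse;dopaminergic_synapse;serotonergic_synapse	0	0	0	0	0	1	high
AURKA	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	low
CDK4	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	1	high
CLIC6	B	dopaminergic_synapse;neuroactive_ligand_receptor	0	0	0	0	0	1	low
CMTM4	B	neuroactive_ligand_receptor;camp_signaling	0	0	0	1	0	0	high
DCTN1	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
DERL1	B	camp_signaling;serotonergic_synapse	0	0	0	1	1	0	high
DGUOK	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
EIF2AK3	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	0	high
FUS	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	0	high
GNB2	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	1	high
GRID2	B	glutamatergic_synapse;neuroactive_ligand_receptor	0	0	0	0	0	1	low
HIST1H1C	B	dopaminergic_synapse;serotonergic_synapse	0	0	0	1	0	0	high
ILK	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
ITPR1	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	1	high
MAP2K1	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
PPP1CB	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
RAF1	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	0	high
SLC39A1	B	neuroactive_ligand_receptor;camp_signaling	0	0	0	1	0	0	high
SNCG	B	camp_signaling;serotonergic_synapse	0	0	0	0	0	1	high
UBR5	B	dopaminergic_synapse;camp_signaling	0	0	0	1	0	1	high
XPO1	B	dopaminergic_synapse;camp_signaling	0	0	0	1	1	1	high
YWHAQ	B	dopaminergic_synapse;camp_signaling	0	0	0	0	0	1	high
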