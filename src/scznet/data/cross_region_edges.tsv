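set_a_gene	set_b_gene	factor_dlpfc	factor_amygdala	pathway
CACNA1C	PCBD1	1	1	serotonergic_synapse
CASP3	DBNL	1	1	serotonergic_synapse
GNAS	FSCN1	1	4	serotonergic_synapse
GNAS	XPO1	3	5	serotonergic_synapse
HTR3A	FITM2	1	1	serotonergic_synapse
HTR3A	HIST1H1C	9	6	serotonergic_synapse
MAPK3	TEK	3	2	serotonergic_synapse
MAPK3	DUSP5	19	6	serotonergic_synapse
PLA2G4A	JAK1	3	1	serotonergic_synapse
PRKCA	FSCN1	1	4	serotonergic_synapse
PRKCA	HIST1H1C	9	6	serotonergic_synapse
PRKCA	AKAP12	3	7	serotonergic_synapse
SLC18A1	EMC7	3	2	serotonergic_synapse
CHRNA3	TMEM219	1	1	neuroactive_ligand_receptor
GABBR1	DDIT3	1	6	neuroactive_ligand_receptor
GRIN1	CAMK2G	1	4	neuroactive_ligand_receptor
GRIN2A	PTK2B	2	2	neuroactive_ligand_receptor
GRIN2B	CAMK2G	1	4	neuroactive_ligand_receptor
LPAR1	FITM2	1	1	neuroactive_ligand_receptor
NR3C1	SMARCC2	2	2	neuroactive_ligand_receptor
PTGER3	RETSAT	1	3	neuroactive_ligand_receptor
VIPR2	FITM2	1	1	neuroactive_ligand_receptor
CACNA1C	PCBD1	1	1	glutamatergic_synapse
GNAS	FSCN1	1	4	glutamatergic_synapse
GNAS	XPO1	3	5	glutamatergic_synapse
GRIN1	CAMK2G	1	4	glutamatergic_synapse
GRIN2A	PTK2B	2	2	glutamatergic_synapse
GRIN2B	CAMK2G	1	4	glutamatergic_synapse
MAPK3	TEK	3	2	glutamatergic_synapse
MAPK3	DUSP5	19	6	glutamatergic_synapse
PLA2G4A	JAK1	3	1	glutamatergic_synapse
PRKCA	FSCN1	1	4	glutamatergic_synapse
PRKCA	HIST1H1C	9	6	glutamatergic_synapse
PRKCA	AKAP12	3	7	glutamatergic_synapse
SHANK3	CRKL	2	1	glutamatergic_synapse
AKT1	SMARCC2	2	2	dopaminergic_synapse
AKT1	FAM110C	3	2	dopaminergic_synapse
AKT1	TEK	3	2	dopaminergic_synapse
AKT1	DCTN1	1	4	dopaminergic_synapse
AKT1	TCOF1	2	4	dopaminergic_synapse
ARRB2	SF3B1	3	2	dopaminergic_synapse
ARRB2	SMARCC2	2	2	dopaminergic_synapse
ARRB2	RPLP0	9	2	dopaminergic_synapse
ARRB2	RPL22	3	3	dopaminergic_synapse
ARRB2	TCOF1	2	4	dopaminergic_synapse
ARRB2	XPO1	3	5	dopaminergic_synapse
ARRB2	HIST1H1C	9	6	dopaminergic_synapse
ARRB2	SF3B2	1	10	dopaminergic_synapse
CACNA1C	PCBD1	1	1	dopaminergic_synapse
CALM1	SF3B1	3	2	dopaminergic_synapse
CALM1	RPL22	3	3	dopaminergic_synapse
CALM1	CAMK2G	1	4	dopaminergic_synapse
CAMK2A	DBNL	1	1	dopaminergic_synapse
CAMK2A	ARL3	3	4	dopaminergic_synapse
CAMK2A	CAMK2G	1	4	dopaminergic_synapse
CAMK2A	DCTN1	1	4	dopaminergic_synapse
GNAS	FSCN1	1	4	dopaminergic_synapse
GNAS	XPO1	3	5	dopaminergic_synapse
GRIN2A	PTK2B	2	2	dopaminergic_synapse
GRIN2B	CAMK2G	1	4	dopaminergic_synapse
GSK3A	RBM8A	1	3	dopaminergic_synapse
GSK3B	C14orf1	3	1	dopaminergic_synapse
GSK3B	SF3B1	3	2	dopaminergic_synapse
GSK3B	TLE1	2	4	dopaminergic_synapse
GSK3B	RNF220	1	4	dopaminergic_synapse
GSK3B	XPO1	3	5	dopaminergic_synapse
PPP2R2B	PPP4C	1	1	dopaminergic_synapse
PRKCA	FSCN1	1	4	dopaminergic_synapse
PRKCA	HIST1H1C	9	6	dopaminergic_synapse
PRKCA	AKAP12	3	7	dopaminergic_synapse
SLC18A1	EMC7	3	2	dopaminergic_synapse
AKT1	SMARCC2	2	2	camp_signaling
AKT1	FAM110C	3	2	camp_signaling
AKT1	TEK	3	2	camp_signaling
AKT1	DCTN1	1	4	camp_signaling
AKT1	TCOF1	2	4	camp_signaling
CACNA1C	PCBD1	1	1	camp_signaling
CALM1	SF3B1	3	2	camp_signaling
CALM1	RPL22	3	3	camp_signaling
CALM1	CAMK2G	1	4	camp_signaling
CAMK2A	DBNL	1	1	camp_signaling
CAMK2A	ARL3	3	4	camp_signaling
CAMK2A	CAMK2G	1	4	camp_signaling
CAMK2A	DCTN1	1	4	camp_signaling
GABBR1	DDIT3	1	6	camp_signaling
GNAS	FSCN1	1	4	camp_signaling
GNAS	XPO1	3	5	camp_signaling
GRIN1	CAMK2G	1	4	camp_signaling
GRIN2A	PTK2B	2	2	camp_signaling
GRIN2B	CAMK2G	1	4	camp_signaling
MAPK3	TEK	3	2	camp_signaling
MAPK3	DUSP5	19	6	camp_signaling
PDE4B	XPO1	3	5	camp_signaling
PDE4D	AKAP12	3	7	camp_signaling
PTGER3	RETSAT	1	3	camp_signaling
RELA	PPP4C	1	1	camp_signaling
RELA	SETD6	3	1	camp_signaling
RELA	MKRN2	3	1	camp_signaling
RELA	MACROD1	1	1	camp_signaling
RELA	AATF	3	2	camp_signaling
RELA	TLE1	2	4	camp_signaling
RELA	XPO1	3	5	camp_signaling
VIPR2	FITM2	1	1	camp_signaling
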