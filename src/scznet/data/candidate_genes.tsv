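gene	factor	dopaminergic_synapse	neuroactive_ligand_receptor	glutamatergic_synapse	camp_signaling	serotonergic_synapse
GNB2	1	Y	-	Y	-	Y
CAMK2G	1	Y	-	-	Y	-
P2RX6	1	-	Y	-	-	-
MAP2K1	1	-	-	-	Y	Y
RAF1	1	-	-	-	Y	Y
CYP2D6	2	-	-	-	-	Y
ITPR1	2	Y	-	Y	-	-
EDNRB	3	-	Y	-	-	-
GHR	3	-	Y	-	-	-
GRID2	3	-	Y	-	-	-
PDE3A	3	-	-	-	Y	-
RRAS2	3	-	-	-	Y	-
S1PR1	5	-	Y	-	-	-
ATP1B2	5	-	-	-	Y	-
GLI3	5	-	-	-	Y	-
PLCB2	9	Y	-	Y	-	Y
TSPO	9	-	Y	-	-	-
VAV1	9	-	-	-	Y	-
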