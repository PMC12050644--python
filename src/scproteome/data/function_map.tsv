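protein_id	group_label
K1C10	keratins
KRT1	keratins
KRT2	keratins
KRT3	keratins
KRT5	keratins
KRT6	keratins
KRT7	keratins
KRT8	keratins
KRT14	keratins
KRT15	keratins
KRT16	keratins
KRT17	keratins
KRT19	keratins
KRT23	keratins
KRT26	keratins
KRT27	keratins
KRT28	keratins
KRT73	keratins
KRT75	keratins
KRT80	keratins
PSMA5	proteasome
PSMA6	proteasome
PSMB1	proteasome
PSMB6	proteasome
DSG1	corneodesmosome
DSC1	corneodesmosome
ASPRV1	filaggrin_processing
CAPNS1	filaggrin_processing
BLMH	filaggrin_processing
CASP14	filaggrin_processing
ARG1	filaggrin_processing
HAL	filaggrin_processing
GGCT	filaggrin_processing
SBSN	ce_processing
ASAH1	ce_processing
ALOX12B	ce_processing
ALOXE3	ce_processing
SERPINB8	ce_processing
FLNA	cytoskeleton
FLNB	cytoskeleton
TTN	cytoskeleton
ARHGEF17	cytoskeleton
VIM	cytoskeleton
GGH	redox
PRDX2	redox
HSPA5	proteostasis
NPEPPS	proteostasis
GAPDH	metabolism
GSDMA	other
ANXA2	other
SRP68	other
ACVR2A	other
LAMA2	other
SBNO1	other
EN2	other
NCCRP1	other
MUC16	other
NAV1	other
GFAP	other
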