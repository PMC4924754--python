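lnc_id	trend	chrom_band	alias	category	overlap_relation	corr_transcript_r	psg_class	parental_gene	parental_band	corr_parental_r	in_table1
RLIM-6	asc	Xq13		overlapping	AS to SLC16A2	0.37					True
ANGPTL1-3	asc	1q25		overlapping	AS to RALGPS2	0.3					True
SENP5-4	asc	3q29	NCBP2-AS2	overlapping	S to NCBP2	-0.054					True
LRRC47-1	desc	1p36	TP73-AS1	overlapping	AS to TP73	0.03					True
WHAMM-2	asc	15q25	SNHG21	overlapping	AS to FSD2	-0.03					False
SERPINC1-1	asc	1q25	GAS5	overlapping	AS to ZBTB37	0.29					False
SNX29P2-3	desc	16p11		overlapping	AS to NPIPL1		P				False
HSFY2-10	desc	Yq11	CD24P4	overlapping	S to CD24		PP	CD24	Yq11		True
CPSF2-2	asc	14q32		overlapping	AS to TRIP11	0.063	PP	PTMA	2q37	-0.32	False
IRF2-3	desc	4q35		linc							False
VKORC1L1-3	desc	7q11	RP13-254B10.1	linc			PP				False
STOM-7	desc	9q33	GGTA1P	linc			UP				True
RALGAPB-1	asc	20q11	SNHG11	linc							False
MC2R-2	asc	18p11	RP11-681N23.1	linc			PP	RPL36A	Xq22		True
SAFB2-3	asc	19p13	SNRPEP4	linc			PP	SNRPE	1q32	0.5	True
KIF20B-7	asc	10q23	SNRPD2P1	linc			PP	SNRPD2	19q13	0.79	False
DNAJC16-1	asc	1p36	CHCHD2P6	linc			PP	CHCHD2	7p11		False
WDR11-7	asc	10q26	RN7SKP167	linc			M	RN7SK	6p12		False
PNRC1-1	asc	6q15	RN7SL336P	linc			M	RN7SL	14q21		False
DLX5-4	asc	7q21	RN7SL252P	linc			M	RN7SL	14q21		False
ZC3H12B-10	asc	Xq11	RN7SL799P	linc			M	RN7SL	14q21		False
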