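lnc_id	lesion	score_d	fold_change	chrom_band	alias	overlap_relation	corr_transcript_r	psg_class	parental_gene	parental_band	corr_parental_r
MEF2C-2	del17	4.98	2.26	5q14	LINC00461	S to MIR9-2					
TRPV4-1	del17	4.04	2.16	12q24	FAM222A-AS1	AS to FAM222A	-0.07				
ROPN1B-7	del17	3.62	1.6	3q21	FAM86JP			PP	FAM86C1	11q13	0.22
TOR1AIP2-5	gain1q	3.81	1.48	1q25							
ANGPTL1-3	gain1q	3.78	1.38	1q25		AS to RALGPS2	0.3				
CD46-4	gain1q	3.43	1.3	1q32		AS to miR-102					
SERPINC1-1	gain1q	3.24	1.38	1q25	GAS5	AS to ZBTB37	0.29				
HNRNPU-1	gain1q	3.12	1.48	1q44	HNRNPU-AS1	AS to COX20	0.18				
TRAF5-1	gain1q	3.11	1.35	1q32	LINC00467						
ANKRD36BP1-1	gain1q	2.9	1.3	1q24	ANKRD36BP1						
NEK3-1	del13	-4.07	0.7	13q14	MRPS31P5			UnP			
FAM60A-6	del13	-3.95	0.68	12p11		S to OVOS2					
FAM70B-1	del13	-3.67	0.79	13q14	GAS6-AS1	AS to GAS6	-0.28				
CYorf15A.1-2	del13	-3.3	0.39	Yq11	TXLNG2P			UnP	TXLNG	Xp22	-0.07
MTRNR2L1-4	del13	-3.28	0.85	17p11				PP	MT-ND2		
ZFYVE1-4	del13	-3.03	0.87	14q24	RN7SL586P			M	RN7SL	14q21	
RNASEH1-7	del13	-2.96	0.81	2p25	TMSB4XP2	AS to COLEC11	0.19	UnP	TMSB4X	Xp22	
KDM5D-3	del13	-2.91	0.66	Yq11							
SLC7A1-1	del13	-2.81	0.82	13q12	MTUS2-AS1	AS to MTUS2	0.19				
SPRYD7-1	del13	-2.7	0.72	13q14	DLEU2	AS to TRIM13	0.09				
RCOR3-1	del13	-2.67	0.87	1q32				PP	RPS25	11q23	
BACH1-2	del13	-2.67	0.84	21q21	GRIK1-AS1	AS to GRIK1	0.18				
CLYBL-1	del13	-2.65	0.76	13q32		S to CLYBL	0.24				
POM121L2-2	del13	3.77	1.8	6p22	ZNF204P			PP			
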