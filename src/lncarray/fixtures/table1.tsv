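lnc_id	normal_dir	MGUS	SMM	MM	PCL	chrom_band	alias	overlap_relation	corr_transcript_r	psg_class	parental_gene	parental_band	corr_parental_r
AC100793.1-1	up	down	down	down	down	17q21	RAMP2-AS1						
ATL3-1	up	down	down	down	down	11q13	C11orf95						
ADAP2-2	up	down	down	down	down	17q11	RN7SL138P			M	RN7SL	14q21	
STOM-7	up	ns	down	down	down	9q33	GGTA1P			UP			
HSFY2-10	up	ns	down	down	down	Yq11	CD24P4	S to CD24		PP	CD24	Yq11	
CISH-3	up	down	ns	down	down	3p21	ZNF652P1	AS to DOCK3	0.053	PP	ZNF652	17q21	0.65
LRRC47-1	up	down	ns	down	down	1p36	TP73-AS1	AS to TP73	0.03				
SEL1L3-6	up	down	down	ns	down	4p15				UnP			
SEMA4B-4	up	down	down	ns	down	15q26							
PQLC2-5	up	down	down	ns	down	1p36	RN7SL277P	AS to CAPZB	-0.26	M	RN7SL	14q21	
SNURF-1	up	down	down	ns	down	15q11		S to SNORD115-116 family					
SNURF-3	up	down	down	ns	down	15q11		S to SNORD115-116 family					
APC-6	down	up	up	up	up	5q22	EPB41L4A-AS1	S to SNORA13					
MON2-2	down	up	up	up	up	12q14		S to Let7i					
ARFIP1-5	down	up	up	up	up	4q13		AS to FBXW7, S to MIR4453	0.03				
PTPDC1-7	down	ns	up	up	up	9q22		AS to MIRLET7DHG					
MC2R-2	down	ns	up	up	up	18p11				PP	RPL36A	Xq22	
SAFB2-3	down	ns	up	up	up	19p13	SNRPEP4			PP	SNRPE	1q32	0.5
SYT8-3	down	ns	up	up	up	11p15	RPL36AP39			PP	RPL36A	Xq22	
CHRDL2-3	down	ns	up	up	up	11q13				PP	RPS12	6q23	0.17
SCYL1-1	down	ns	up	up	up	11q13	MALAT1						
TRPV2-1	down	ns	up	up	up	17p11	LRRC75A-AS1	S to SNORD49B, 49A, 65					
LIPG-3	down	ns	up	up	up	18q21	SNHG22						
USP25-2	down	ns	up	up	up	21q21		S to SNORD74, MIR99AHG					
C3orf25-2	down	ns	up	up	up	3q21	RPL32P3	S to SNORA7B		UnP	RPL32	3p25	0.47
AP1M2-1	down	ns	up	up	up	19p13	ILF3-AS1						
ANGPTL1-3	down	ns	up	up	up	1q25		AS to RALGPS2	0.3				
SENP5-4	down	ns	up	up	up	3q29	NCBP2-AS2						
PAIP1-3	down	ns	up	up	up	5p12	RPL29P12	AS to NNT	-0.054	PP	RPL29	3p21	0.7
ABCB5-3	down	ns	up	up	up	7p21	RPL23P8			PP	RPL23	17q12	
RLIM-6	down	ns	up	up	up	Xq13		AS to SLC16A2	0.37				
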