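cpg_id	cpg_gene	cpg_chr	cpg_pos	protein_gene	protein_id	protein_chr	gene_start	gene_end	p_pqtm	beta_pqtm	eqtm_transcript	eqtm_gene	eqtm_p	eqtm_beta
cg07708453	PRDM2	1	14032034	PAPPA	4148-49_2	9	118916083	119164601	3.10e-16	0.262	ENSG00000116731	PRDM2	2.52e-6	0.13
cg19393755	CPSF4L	17	71258101	PAPPA	4148-49_2	9	118916083	119164601	2.03e-14	-0.246	ENSG00000179604	CDC42EP4	3.58e-11	0.132
cg10831642	SH3PXD2A	10	105378344	PAPPA	4148-49_2	9	118916083	119164601	8.19e-12	-0.246	ENSG00000107957	SH3PXD2A	9.03e-32	0.287
cg26272069	GABBR1	6	29591706	PAPPA	4148-49_2	9	118916083	119164601	9.25e-12	-0.224	ENSG00000204681	GABBR1	3.80e-8	-0.073
cg20290167	METRNL	17	81040724	PAPPA	4148-49_2	9	118916083	119164601	5.58e-11	-0.212	ENSG00000176845	METRNL	2.77e-5	0.091
cg07839457	NLRC5	16	57023022	CD48	3292-75_1	1	160648536	160681641	1.10e-21	-0.306				
cg08159663	NLRC5	16	57022486	CD48	3292-75_1	1	160648536	160681641	3.38e-12	-0.246	ENSG00000140853	NLRC5	8.26e-10	0.213
cg07839457	NLRC5	16	57023022	B2M	3485-28_2	15	45003675	45011075	7.60e-20	-0.292				
cg16411857	NLRC5	16	57023191	B2M	3485-28_2	15	45003675	45011075	1.94e-15	-0.256				
cg00218406	HCP5	6	31431407	B2M	3485-28_2	15	45003675	45011075	3.97e-13	-0.234	ENSG00000206337	HCP5	7.78e-102	0.454
cg08099136	PSMB8	6	32811251	B2M	3485-28_2	15	45003675	45011075	4.80e-11	-0.214	ENSG00000204264	PSMB8	1.96e-23	0.258
cg07839457	NLRC5	16	57023022	CXCL10	4141-79_1	4	76942273	76944650	8.06e-19	-0.283				
cg07839457	NLRC5	16	57023022	FCGR3B	3311-27_1	1	161592986	161601753	1.02e-18	-0.307				
cg08159663	NLRC5	16	57022486	FCGR3B	3311-27_1	1	161592986	161601753	1.44e-14	-0.29	ENSG00000140853	NLRC5	8.26e-10	0.213
cg16411857	NLRC5	16	57023191	FCGR3B	3311-27_1	1	161592986	161601753	3.79e-13	-0.26				
cg07839457	NLRC5	16	57023022	LAG3	5099-14_3	12	6881678	6887621	1.29e-17	-0.274				
cg08159663	NLRC5	16	57022486	LAG3	5099-14_3	12	6881678	6887621	9.22e-13	-0.246	ENSG00000140853	NLRC5	8.26e-10	0.213
cg07839457	NLRC5	16	57023022	CD163	5028-59_1	12	7623409	7656489	1.83e-15	-0.256				
cg07839457	NLRC5	16	57023022	CXCL11	3038-9_2	4	76954835	76962568	1.13e-13	-0.246				
cg10604476	ICAM5	19	10403908	ICAM5	5124-69_3	19	10400657	10407454	6.09e-25	0.356	ENSG00000105376	ICAM5	2.22e-9	0.186
cg03650189	ICAM5	19	10405083	ICAM5	5124-69_3	19	10400657	10407454	1.22e-24	0.344	ENSG00000105376	ICAM5	1.68e-5	0.129
cg22910295	ICAM5	19	10403862	ICAM5	5124-69_3	19	10400657	10407454	3.72e-24	0.339	ENSG00000105376	ICAM5	2.37e-6	-0.134
cg15011409	ICAM5	19	10405226	ICAM5	5124-69_3	19	10400657	10407454	5.96e-23	0.331	ENSG00000105376	ICAM5	2.66e-12	0.198
cg21994045	ICAM5	19	10403936	ICAM5	5124-69_3	19	10400657	10407454	4.18e-17	0.291	ENSG00000105376	ICAM5	1.21e-5	-0.148
cg10773601	CLEC11A	19	51226046	CLEC11A	4500-50_2	19	51226586	51228974	8.06e-27	-0.341	ENSG00000105472	CLEC11A	1.06e-71	0.424
cg16651537	CLEC11A	19	51226536	CLEC11A	4500-50_2	19	51226586	51228974	1.67e-24	-0.326	ENSG00000105472	CLEC11A	3.54e-63	0.434
cg05575921	AHRR	5	373378	PIGR	3216-2_2	1	207101863	207119811	8.08e-16	-0.264	ENSG00000180104	EXOC3	1.19e-6	0.063
cg18419358		6	158384009	GP1BA	4990-87_1	17	4835592	4838325	2.52e-12	0.228				
cg27535410	PRTN3	19	846354	PRTN3	3514-49_2	19	840963	848175	1.21e-11	-0.219				
cg13028630	C4B/C4A	6	31964754	C4A/C4B	4481-34_2	6	31937353	32079643	1.38e-11	-0.246				
cg09488502	SIGLEC5	19	52134289	SIGLEC14	5125-6_3	19	52145806	52150054	4.89e-11	0.22				
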