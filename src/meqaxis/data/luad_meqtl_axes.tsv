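cpg_id	snp_id	gene_symbol	location	cpg_position_alt	alleles	beta_sign_tissue	meqtl_p_tissue	beta_sign_blood	meqtl_p_blood	tumor_meth_level	tumor_expr_level	r	cases_n0	cases_n1	cases_n2	controls_n0	controls_n1	controls_n2	maf_cases	maf_controls	or_value	ci_low	ci_high	p_value
cg19220282	rs66719815	SLC1A4	chr2:65212470	NA	T>C	+	6.36E-15	+	9.93E-201	Low	High	-0.42	2108	1183	162	2182	1331	197	0.218	0.232	0.92	0.85	0.99	0.044
cg09596674	rs939408	LRRC2	chr3:46599079	chr3:46607350	C>A	-	1.75E-05	-	6.89E-08	High	Low	-0.32	2521	868	64	2623	1002	85	0.144	0.158	0.89	0.82	0.98	0.019
cg10700718	rs12680375	MYOM2	chr8:1988076	NA	G>A	-	0.02	-	1.38E-06	Low	Low	0.35	2205	1108	140	2462	1125	123	0.201	0.185	1.11	1.02	1.21	0.013
cg04065210	rs328890	DPY19L1	chr7:35013449	NA	G>A	+	0.02	+	8.01E-39	Low	High	-0.48	1483	1577	393	1704	1612	394	0.342	0.323	1.08	1.01	1.16	0.027
cg04571833	rs750373	RAPGEF4	chr2:173833960	NA	T>C	+	1.99E-14	+	3.80E-20	Low	Low	0.30	1035	1701	717	1178	1836	696	0.454	0.435	1.08	1.01	1.15	0.025
cg16110827	rs3743281	SEMA6D	chr15:48056958	NA	C>T	-	2.24E-19	-	1.63E-213	Low	Low	0.49	2365	987	101	2457	1130	123	0.172	0.185	0.91	0.84	0.99	0.042
cg03230154	rs2885221	ZNF492	chr19:22839387	NA	A>G	+	2.01E-06	+	5.06E-47	High	Low	-0.46	2527	854	72	2619	1010	81	0.145	0.158	0.90	0.82	0.99	0.023
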