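probeset	type	adj_p	fc_elder_young	direction
hsa-miR-199a-3p_st	miRNA	0.016454	0.331	DOWN
hsa-miR-628-3p_st	miRNA	0.015405	0.385	DOWN
hsa-miR-30e-star_st	miRNA	0.032863	0.393	DOWN
hsa-let-7i_st	miRNA	0.004641	0.455	DOWN
hsa-miR-146b-5p_st	miRNA	0.040513	0.466	DOWN
hsa-let-7g_st	miRNA	0.015405	0.468	DOWN
hsa-miR-584_st	miRNA	0.014044	0.524	DOWN
hsa-miR-25_st	miRNA	0.006466	0.547	DOWN
hsa-let-7a_st	miRNA	0.001976	0.554	DOWN
hsa-miR-126_st	miRNA	0.032863	0.555	DOWN
hsa-miR-629_st	miRNA	0.015405	0.562	DOWN
hsa-miR-98_st	miRNA	0.032863	0.582	DOWN
hsa-miR-26b-star_st	miRNA	0.040513	0.583	DOWN
hsa-miR-146a_st	miRNA	0.032603	0.591	DOWN
hsa-miR-421_st	miRNA	0.048753	0.623	DOWN
hsa-let-7c_st	miRNA	0.015405	0.674	DOWN
hsa-miR-26a_st	miRNA	0.032863	0.743	DOWN
hsa-let-7d_st	miRNA	0.032690	0.769	DOWN
HBII-85-20_x_st	snoRNA	0.042958	1.300	UP
14qII-1_x_st	snoRNA	0.032863	1.330	UP
ENSG00000200307_st	snoRNA	0.048753	1.355	UP
ACA36_x_st	snoRNA	0.035892	1.419	UP
hsa-miR-93-star_st	miRNA	0.020493	1.425	UP
ENSG00000200377_st	snoRNA	0.001828	1.438	UP
U84_st	snoRNA	0.044495	1.465	UP
hsa-miR-425-star_st	miRNA	0.016454	1.484	UP
hsa-miR-345_st	miRNA	0.032863	1.539	UP
HBII-180C_st	snoRNA	0.048152	1.539	UP
hsa-miR-1228-star_st	miRNA	0.040755	1.542	UP
U53_st	snoRNA	0.032863	1.590	UP
U43_x_st	snoRNA	0.031213	1.591	UP
U43_st	snoRNA	0.031213	1.605	UP
ENSG00000212523_x_st	snoRNA	0.031213	1.618	UP
hsa-miR-423-3p_st	miRNA	0.017498	1.622	UP
HBII-289_st	snoRNA	0.025374	1.646	UP
hsa-miR-339-5p_st	miRNA	0.006466	1.657	UP
U52_st	snoRNA	0.016454	1.657	UP
HBII-180A_x_st	snoRNA	0.039280	1.667	UP
U83_st	snoRNA	0.046181	1.692	UP
hsa-miR-744_st	miRNA	0.017561	1.694	UP
hsa-miR-330-3p_st	miRNA	0.025221	1.736	UP
hsa-miR-1307_st	miRNA	0.015405	1.790	UP
hsa-miR-941_st	miRNA	0.040513	1.880	UP
hsa-miR-944_st	miRNA	0.009982	1.880	UP
hsa-miR-491-5p_st	miRNA	0.020920	1.884	UP
U25_st	snoRNA	0.005814	1.889	UP
hsa-miR-23a-star_st	miRNA	0.028898	1.915	UP
hsa-miR-501-5p_st	miRNA	0.004144	1.951	UP
U91_s_st	snoRNA	0.006699	1.995	UP
hsa-miR-500_st	miRNA	0.001976	2.000	UP
hsa-miR-432_st	miRNA	0.023427	2.030	UP
hsa-miR-1825_st	miRNA	0.015405	2.093	UP
hsa-miR-193b-star_st	miRNA	0.015405	2.386	UP
hsa-miR-1281_st	miRNA	0.004641	2.509	UP
hsa-miR-1228_st	miRNA	0.000146	2.948	UP
hsa-miR-198_st	miRNA	0.000239	5.170	UP
hsa-miR-551b-star_st	miRNA	0.000443	5.398	UP
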