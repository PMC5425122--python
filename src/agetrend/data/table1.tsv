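probeset	type	pearson_r	fc_last_first	trend
U38B_st	CDBox	-0.947	0.364	decreasing
hsa-miR-125b_st	miRNA	-0.941	0.569	decreasing
hsa-miR-146a_st	miRNA	-0.917	0.561	decreasing
hsa-miR-19b_st	miRNA	-0.913	0.530	decreasing
hsa-miR-194_st	miRNA	-0.906	0.656	decreasing
hsa-miR-29a_st	miRNA	-0.902	0.655	decreasing
hsa-miR-130a_st	miRNA	-0.901	0.628	decreasing
hsa-let-7g_st	miRNA	-0.899	0.434	decreasing
hsa-let-7a_st	miRNA	-0.897	0.578	decreasing
hsa-miR-146b-5p_st	miRNA	-0.896	0.457	decreasing
hsa-miR-25_st	miRNA	-0.890	0.574	decreasing
U38B_x_st	CDBox	-0.884	0.457	decreasing
hsa-miR-15a_st	miRNA	-0.874	0.465	decreasing
hsa-miR-126_st	miRNA	-0.871	0.554	decreasing
hsa-miR-363_st	miRNA	-0.865	0.607	decreasing
hsa-let-7i_st	miRNA	-0.853	0.498	decreasing
hsa-miR-629_st	miRNA	-0.847	0.612	decreasing
hsa-miR-584_st	miRNA	-0.841	0.592	decreasing
hsa-miR-30b_st	miRNA	-0.839	0.476	decreasing
ACA40_x_st	HAcaBox	-0.800	0.282	decreasing
ACA8_x_st	HAcaBox	-0.781	0.644	decreasing
hsa-miR-1271_st	miRNA	0.768	1.497	increasing
U48_st	CDBox	0.771	1.601	increasing
ENSG00000212523_x_st	snoRNA	0.776	1.670	increasing
hsa-miR-500-star_st	miRNA	0.811	1.616	increasing
U46_st	CDBox	0.820	1.510	increasing
U25_st	CDBox	0.826	1.642	increasing
U43_x_st	CDBox	0.831	1.539	increasing
U43_st	CDBox	0.838	1.557	increasing
U91_s_st	scaRna	0.840	1.884	increasing
hsa-miR-1280_st	miRNA	0.848	1.659	increasing
ACA16_st	HAcaBox	0.853	1.498	increasing
hsa-miR-339-5p_st	miRNA	0.856	1.561	increasing
HBII-180A_x_st	CDBox	0.858	1.616	increasing
hsa-miR-663_st	miRNA	0.865	1.500	increasing
hsa-miR-1308_st	miRNA	0.869	1.604	increasing
hsa-miR-25-star_st	miRNA	0.878	1.658	increasing
hsa-miR-1275_st	miRNA	0.883	1.855	increasing
hsa-miR-149-star_st	miRNA	0.884	1.503	increasing
hsa-miR-1228-star_st	miRNA	0.888	1.685	increasing
hsa-miR-766_st	miRNA	0.894	1.730	increasing
hsa-miR-197_st	miRNA	0.894	1.657	increasing
hsa-miR-345_st	miRNA	0.897	1.683	increasing
hsa-miR-574-5p_st	miRNA	0.898	1.585	increasing
hsa-miR-505-star_st	miRNA	0.907	1.535	increasing
hsa-miR-423-3p_st	miRNA	0.909	1.656	increasing
hsa-miR-150-star_st	miRNA	0.913	1.716	increasing
hsa-miR-432_st	miRNA	0.921	2.327	increasing
hsa-miR-1281_st	miRNA	0.921	2.778	increasing
hsa-miR-877_st	miRNA	0.923	1.889	increasing
hsa-miR-486-3p_st	miRNA	0.925	1.678	increasing
hsa-miR-491-5p_st	miRNA	0.928	1.929	increasing
hsa-miR-23a-star_st	miRNA	0.929	2.524	increasing
hsa-miR-339-3p_st	miRNA	0.929	1.520	increasing
hsa-miR-502-3p_st	miRNA	0.931	1.759	increasing
hsa-miR-1307_st	miRNA	0.938	1.836	increasing
hsa-miR-328_st	miRNA	0.944	1.883	increasing
hsa-miR-500_st	miRNA	0.946	2.460	increasing
hsa-miR-744_st	miRNA	0.949	1.845	increasing
hsa-miR-193a-5p_st	miRNA	0.952	2.166	increasing
hsa-miR-574-3p_st	miRNA	0.954	1.811	increasing
hsa-miR-330-3p_st	miRNA	0.954	1.953	increasing
hsa-miR-941_st	miRNA	0.954	2.395	increasing
hsa-miR-425-star_st	miRNA	0.963	1.653	increasing
hsa-miR-423-5p_st	miRNA	0.963	1.998	increasing
hsa-miR-1301_st	miRNA	0.969	1.813	increasing
hsa-miR-378_st	miRNA	0.975	1.537	increasing
hsa-miR-501-5p_st	miRNA	0.978	2.688	increasing
hsa-miR-93-star_st	miRNA	0.982	1.646	increasing
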