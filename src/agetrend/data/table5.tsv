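probeset	mirna	r_sw	fc_last_first	fc_elder_young	adj_p	rq_discovery	p_discovery	rq_validation	p_validation
hsa-miR-1281_st	miR-1281	0.921	2.778	2.509	4.64E-03	1.127	6.60E-01	NA	NA
hsa-let-7i_st	let-7i	-0.853	0.498	0.455	4.64E-03	0.566	2.86E-02	0.226	1.53E-07
hsa-miR-30b_st	miR-30b	-0.839	0.476	0.503	1.05E-01	0.777	1.07E-01	0.419	7.66E-07
hsa-miR-15a_st	miR-15a	-0.874	0.465	0.525	9.39E-02	0.632	1.21E-01	0.219	1.23E-07
hsa-let-7g_st	let-7g	-0.899	0.434	0.468	1.54E-02	0.578	1.14E-02	0.199	1.05E-08
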