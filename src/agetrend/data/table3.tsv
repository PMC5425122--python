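name	analysis	daa_id	direction	tissue	reference
let-7a	SW & Diff exp	DAA2533	decreases	Foreskin	Hackl et al. (2010)
let-7a	SW & Diff exp	NA	decreases	PBMC	Serna et al. (2012)
let-7g	SW & Diff exp	DAA2476	decreases	Foreskin	Hackl et al. (2010)
let-7g	SW & Diff exp	NA	decreases	PBMC	Serna et al. (2012)
let-7i	SW & Diff exp	DAA2561	decreases	T Cell	Hackl et al. (2010)
let-7i	SW & Diff exp	DAA2503	decreases	Foreskin	Hackl et al. (2010)
miR-125b	SW	DAA2517	decreases	Foreskin	Hackl et al. (2010)
miR-126	SW & Diff exp	DAA2605	decreases	Blood	ElSharawy et al. (2012)
miR-126	SW & Diff exp	DAA2504	decreases	Foreskin	Hackl et al. (2010)
miR-1281	SW & Diff exp	NA	increases	PBMC	Serna et al. (2012)
miR-130a	SW	DAA2471	decreases	Foreskin	Hackl et al. (2010)
miR-130a	SW	DAA2006	decreases	Blood, Immune System	Noren Hooten et al. (2010)
miR-15a	SW	DAA2553	decreases	T Cell	Hackl et al. (2010)
miR-19b	SW	DAA2548	decreases	T Cell	Hackl et al. (2010)
miR-19b	SW	NA	decreases	PBMC	Serna et al. (2012)
miR-26a	Diff exp	NA	decreases	PBMC	Serna et al. (2012)
miR-30b	SW	DAA2486	decreases	Foreskin	Hackl et al. (2010)
miR-423-3p	SW & Diff exp	DAA2545	increases	Foreskin	Hackl et al. (2010)
miR-423-3p	SW & Diff exp	NA	increases	PBMC	Serna et al. (2012)
miR-98	Diff exp	DAA2576	decreases	T Cell	Hackl et al. (2010)
U43	SW & Diff exp	NA	increases	PBMC	Serna et al. (2012)
U52	Diff exp	NA	increases	PBMC	Serna et al. (2012)
U91	SW & Diff exp	NA	increases	PBMC	Serna et al. (2012)
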