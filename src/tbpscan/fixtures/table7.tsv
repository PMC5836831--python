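gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
AR	rs763353257	aagggaagta	g	-	gtggaagatt	30	21	↑	6	1e-06	A	(hypothetically) higher risks of androgenetic alopecia and androgen-induced premature senescence in adult men
AR	rs749306567	aagggaagta	g	a	gtggaagatt	30	15	↑	11	1e-06	A	(hypothetically) higher risks of androgenetic alopecia and androgen-induced premature senescence in adult men
AR	rs377711437	cagcactgca	g	a	ccacgacccg	75	66	↑	2	0.05	D	(hypothetically) higher risks of androgenetic alopecia and androgen-induced premature senescence in adult men
MTHFR	rs780207553	cacgcactct	g	a	ggcctgagct	74	38	↑	12	1e-06	A	(hypothetically) higher risk of pre-eclampsia
MTHFR	rs749532075	tccctcccca	c	t	gcactctggg	74	50	↑	7	1e-06	A	(hypothetically) higher risk of pre-eclampsia	extra_neutral_allele
MTHFR	rs771960561	cctctgttcc	c	t	tccccacgca	74	66	↑	3	1e-02	B	(hypothetically) higher risk of pre-eclampsia	rank_mismatch
MTHFR	rs773214376	tgcctctgtt	c	t	cctccccacg	74	66	↑	2	0.05	D	(hypothetically) higher risk of pre-eclampsia
MTHFR	rs566478202	ggtgcctctg	t	g	tccctcccca	74	85	↓	2	0.05	D	(hypothetically) higher risk of adverse pregnancy outcomes
MTHFR	rs752181249	gaggatctac	a	c	gccatcagct	27	35	↓	4	1e-03	B	(hypothetically) higher risk of adverse pregnancy outcomes
DNMT1	rs570287204	gtgggggggg	-	gtg	tgtgtgcccg	52	23	↑	11	1e-06	A	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs534819409	cgtggggggg	g	t	ggcctgagct	52	30	↑	7	1e-06	A	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs553454792	gcgtgggggg	g	t	gtgtgtgccc	52	23	↑	11	1e-06	A	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs558447661	cgtggagctt	g	t	gacgagccca	72	29	↑	15	1e-06	A	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs535899986	cccagcaaac	c	t	gtggagcttg	72	58	↑	5	1e-03	B	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs143796354	cacctcccag	c	a	aaaccgtgga	72	26	↑	20	1e-06	A	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs756103340	gcggcgcgca	g	a	cggcagttgg	92	79	↑	3	1e-03	B	(hypothetically) under stress, higher risk of epigenetic disorders of fetal and newborn brain development
DNMT1	rs758026532	ccagcaaacc	g	t	tggagcttgg	72	88	↓	4	1e-03	B	(hypothetically) higher risks of activation of protooncogenes in cancer	extra_neutral_allele
DNMT1	rs772821225	gtctccaata	a	c	atgcagctgg	7	8	↓	2	0.05	D	(hypothetically) higher risks of activation of protooncogenes in cancer
CYP17A1	rs758657961	ctggagttga	g	a	ccagcccttg	56	30	↑	11	1e-06	A	(hypothetically) higher risk of hyperandrogenism in polycystic ovary syndrome
CYP17A1	rs373488849	tgccctggag	t	c	tgagccagcc	56	70	↓	4	1e-03	B	(hypothetically) higher risk of fertility impairments
NR5A1	rs147497093	gttcagcaag	c	t	acaagagaaa	19	6	↑	17	1e-06	A	(hypothetically) higher risks of adrenal tumors and endometriosis
NR5A1	rs535432539	cgctgcttcc	g	a	cttcgtaagt	31	18	↑	9	1e-06	A	(hypothetically) higher risks of adrenal tumors and endometriosis
NR5A1	rs553326158	gcgctgcttc	c	t	gcttcgtaag	31	26	↑	3	1e-02	C	(hypothetically) higher risks of adrenal tumors and endometriosis
NR5A1	rs143242438	caccctcatc	c	t	ggtgtgagag	31	21	↑	6	1e-06	A	(hypothetically) higher risks of adrenal tumors and endometriosis
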