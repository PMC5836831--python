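gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
HBB	rs397509430	gggctgggca	t	-	atacaacagt	5	29	↓	34	1e-06	A	malaria resistance and thalassemia
HBB	rs33980857	gggctgggca	t	a,g,c	atacaacagt	5	21	↓	27	1e-06	A	malaria resistance and thalassemia
HBB	rs34598529	ggctgggcat	a	g	aaagtcaggg	5	18	↓	24	1e-06	A	malaria resistance and thalassemia
HBB	rs33931746	gctgggcata	a	g,c	aagtcagggc	5	11	↓	14	1e-06	A	malaria resistance and thalassemia
HBB	rs33981098	agggctgggc	a	g,c	taaaagtcag	5	9	↓	10	1e-06	A	malaria resistance and thalassemia
HBB	rs34500389	cagggctggg	c	a,t,g	ataaaagtca	5	6	↓	3	1e-02	C	(hypothetically) the same disease; wt-mut heterozygotes more viable than either homozygote
HBB	rs63750953	ctgggcataa	aa	-	gtcagggcag	5	8	↓	9	1e-06	A	(hypothetically) the same disease; wt-mut heterozygotes more viable than either homozygote
HBB	rs281864525	tgggcataaa	a	c	gtcagggcag	5	7	↓	7	1e-06	A	(hypothetically) the same disease; wt-mut heterozygotes more viable than either homozygote
HBB	rs117785782	ggctgagggt	t	c	tgaagtccaa	28	39	↓	7	1e-06	A	(hypothetically) the same disease; wt-mut heterozygotes more viable than either homozygote
HBD	rs35518301	caggaccagc	a	g	taaaaggcag	4	8	↓	11	1e-06	A	malaria resistance and thalassemia
HBD	rs34166473	aggaccagca	t	c	aaaaggcagg	4	8	↓	18	1e-06	A	(hypothetically) the same disease; wt-mut heterozygotes more viable
HBG2	rs745580140	ggagttgctc	ta	-	cacaagctct	11	22	↓	10	1e-06	A	(hypothetically) malaria resistance and thalassemia
ACKR1	rs2814778	ttggctctta	t	c	cttggaagca	10	12	↓	4	1e-03	B	low white-blood-cell count and resistance to malaria; (hypothetically) pre-eclampsia
MBL2	rs72661131	tctatttcta	t	c	atagcctgca	2	4	↓	12	1e-06	A	variable immunodeficiency, pre-eclampsia, stroke; (hypothetically) recurrent vulvovaginal infections
MBL2	rs562962093	atctatttct	a	g	tatagcctgc	2	5	↓	15	1e-06	A	(hypothetically) the same diseases; higher risks of recurrent vulvovaginal infections
MBL2	rs567653539	tttctatata	g	a	cctgcaccca	2	1	↑	12	1e-06	A	(hypothetically) reduced risks of recurrent vulvovaginal infections
MMP12	rs2276109	gatatcaact	a	g	tgagtcactc	11	14	↓	3	1e-02	C	lower risk of psoriasis, systemic sclerosis, asthma; (hypothetically) higher risk of ovarian hyperstimulation syndrome
MMP12	rs572527200	gatgatatca	a	g	ctatgagtca	11	14	↓	3	1e-02	C	(hypothetically) higher risk of ovarian hyperstimulation syndrome
F2	rs564528021	agttcaacat	t	c	aacccagagg	13	9	↑	7	1e-06	A	(hypothetically) high risk of pre-eclampsia
F2	rs752364393	caacattaac	c	t	cagaggggtc	13	11	↑	3	1e-03	B	(hypothetically) high risk of pre-eclampsia
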