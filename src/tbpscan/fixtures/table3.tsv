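gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
LEP	rs201381696	tcgggccgct	a	g	taagaggggc	4	12	↓	17	1e-06	A	hypoleptinemia elevates risk of obesity
LEP	rs200487063	tgatcgggcc	g	a	ctataagagg	4	2	↑	6	1e-06	A	(hypothetically) hyperleptinemia elevates risk of hypertension in obesity
LEP	rs34104384	ccgctataag	a	t	ggggcgggca	4	3	↑	4	1e-02	C	(hypothetically) hyperleptinemia elevates risk of hypertension in obesity
GCG	rs183433761	gctggagagt	a	g	tataaaagca	0.9	1.6	↓	17	1e-06	A	resistance to obesity during high-fat diet; (hypothetically) hypoglucagonemia lowers pregnancy probability and serum insulin in pregnancy
GCG	rs757035851	tatataaaag	cag	-	tgcgccttgg	0.9	1.1	↓	3	1e-03	B	(hypothetically) hypoglucagonemia lowers pregnancy probability and serum insulin in pregnancy
GH1	rs11568827	aggggccagg	g	-	tataaaaagg	1.5	1.4	=	1	1	E	short stature (EMSA: unknown TF-binding site lost, not TATA box)
GH1	rs796237787	gaaggggcca	g	-	ggtataaaaa			=				(hypothetically) higher risk of GH1-deficiency clinical syndrome	incomplete
GH1	rs768454929	agggtataaa	a	c	agggcccaca	1.5	2.6	↓	7	1e-06	A	(hypothetically) higher risk of GH1-deficiency clinical syndrome
GH1	rs761695685	gccagggtat	a	g	aaaagggccc	1.5	5.8	↓	19	1e-06	A	(hypothetically) higher risk of GH1-deficiency clinical syndrome
GH1	rs774326004	ccagggtata	a	t	aaagggccca	1.5	0.9	↑	7	1e-06	A	(hypothetically) higher risks of acromegaly
GH1	rs777003420	aaggggccag	g	t	gtataaaaag	1.5	1.3	↑	3	0.05	D	(hypothetically) higher risks of acromegaly
INS	rs5505	agatcactgt	c	t	cttctgccat	53	44	↑	4	1e-03	B	type 1 diabetes after neonatal diabetes mellitus; (hypothetically) hyperinsulinemia elevates placental leptin causing neonatal macrosomia
INS	rs563207167	tcagccctgc	c	t	tgtctcccag	53	44	↑	4	1e-03	B	(hypothetically) hyperinsulinemia elevates placental leptin causing neonatal macrosomia
INS	rs11557611	gatcactgtc	c	t	ttctgccatg	53	60	↓	2	0.05	D	(hypothetically) hypoinsulinemia slows down fetal growth
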