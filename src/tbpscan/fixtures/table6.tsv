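gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
PROC	rs528817178	cctttcattc	c	t	gcttccacct	27	21	↑	5	1e-06	A	(hypothetically) higher risk of tumor cell invasion
PROC	rs539608065	ctttcattcc	g	a	cttccacctg	27	22	↑	4	1e-03	B	(hypothetically) higher risk of tumor cell invasion
PROC	rs539731824	ttgtggttat	g	a	gattaactcg	10	6	↑	8	1e-06	A	(hypothetically) higher risk of tumor cell invasion
PROC	rs756414294	ggcgcggcac	c	t	agcaccagct	121	27	↑	25	1e-06	A	(hypothetically) higher risk of tumor cell invasion
PROC	rs777687270	ggcaccagca	c	t	cagctgcccg	121	59	↑	13	1e-06	A	(hypothetically) higher risk of tumor cell invasion
PROC	rs746382956	tgcccgcaga	g	a	gtgagcttcc	121	44	↑	19	1e-06	A	(hypothetically) higher risk of tumor cell invasion
PROC	rs542626506	cacacaggga	c	t	agccctttca	27	31	↓	3	1e-02	C	(hypothetically) high risks of thrombosis, inflammation, and pregnancy loss
PROC	rs61731661	ccctttcatt	c	t	cgcttccacc	27	29	↓	5	0.05	D	(hypothetically) high risks of thrombosis, inflammation, and pregnancy loss
F8	rs781855957	acggcggcag	c	t	ggaagaggga	75	49	↑	8	1e-06	A	(hypothetically) higher risk of thrombosis
THBD	rs13306848	agggagggcc	g	a	ggcacttata	2	2	=	1	1	E	thrombosis (LUC: TF site damaged, not TATA)
THBD	rs568801899	caatccgagt	g	a	tgcggcatca	45	70	↓	6	1e-06	A	(hypothetically) higher risks of placental failure and fetal loss
F3	rs563763767	ccctttatag	c	t	gcgcggggca	3	2	↑	6	1e-06	A	myocardial infarction; thrombosis; (hypothetically) higher risk of ovarian cancer
F3	rs779755900	atctcgccgc	-	30bp	caactggtag	90	10	↑	43	1e-06	A	(hypothetically) higher risk of ovarian cancer
F3	rs749456955	gatctcgccg	c	a	caactggtag	90	75	↑	4	1e-03	B	(hypothetically) higher risk of ovarian cancer
F3	rs746842194	cgatctcgcc	-	17bp	gccaactggt	90	31	↑	15	1e-06	A	(hypothetically) higher risk of ovarian cancer
F3	rs754815577	ctcgatctcg	-	18bp	ccgccaactg	90	32	↑	17	1e-06	A	(hypothetically) higher risk of ovarian cancer
F3	rs768753666	ggaacccgct	c	g	gatctcgccg	90	117	↓	5	1e-06	A	(hypothetically) lower risk of ovarian cancer
F3	rs774688955	cgccacggaa	c	t	ccgctcgatc	90	101	↓	2	0.05	D	(hypothetically) lower risk of ovarian cancer
F7	-33a>c	ccttggaggc	a	c	gagaactttg	53	62	↓	3	1e-02	C	moderate bleeding; (hypothetically) lower risk of ovarian cancer
F7	rs749691733	agaactttgc	c	t	cgtcagtccc	53	66	↓	4	1e-03	B	(hypothetically) lower risk of ovarian cancer
F7	rs367732974	aactttgccc	g	a	tcagtcccat	53	47	↑	2	0.05	D	(hypothetically) higher risk of ovarian cancer
F7	rs549591993	gcccgtcagt	c	a	ccatggggaa	53	25	↑	13	1e-06	A	(hypothetically) higher risk of ovarian cancer
F7	rs777947114	agagaacttt	g	a	cccgtcagtc	53	19	↑	19	1e-06	A	(hypothetically) higher risk of ovarian cancer
F7	rs770113559	gtcacccttg	g	a	aggcagagaa	53	41	↑	5	1e-06	A	(hypothetically) higher risk of ovarian cancer
F7	rs754814507	cctcccccat	c	t	cctctgtcac	53	45	↑	3	1e-03	B	(hypothetically) higher risk of ovarian cancer
F11	rs754739433	tctgggaatt	a	g	tttttagtaa	4	5	↓	2	0.05	D	(hypothetically) hereditary factor XI deficiency, high risk of spontaneous primary hemorrhage
F11	rs780731761	ttatttttag	t	a	aaaggaaatt	4	7	↑	8	1e-06	A	(hypothetically) hereditary factor XI deficiency, high risk of spontaneous primary hemorrhage	delta_sign_conflict
F11	rs747652067	tatttttagt	a	g	aaggaaattt	4	7	↑	9	1e-06	A	(hypothetically) hereditary factor XI deficiency, high risk of spontaneous primary hemorrhage	delta_sign_conflict
F11	rs374761594	catttgtcta	c	t	tgaagcacac	13	10	↑	3	1e-03	B	(hypothetically) higher risk of angioneurotic edema
F11	rs759231858	acaccaacca	g	t	aataacgaag	13	4	↑	17	1e-06	A	(hypothetically) higher risk of angioneurotic edema
F11	rs752308147	ccagaataac	g	a	aagctcgata	13	9	↑	6	1e-06	A	(hypothetically) higher risk of angioneurotic edema
F9	rs371045754	tggtacaact	a	c	atcgacctta	6	10	↓	5	1e-06	A	(hypothetically) higher risk of hemophilia B
F9	rs750827465	tttggtacaa	c	t	taatcgacct	6	4	↑	7	1e-06	A	(hypothetically) higher risk of myocardial fibrosis
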