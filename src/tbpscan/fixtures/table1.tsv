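gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
ESR2	rs35036378	cctctcggtc	t	g	ttaaaaggaa	6	8	↓	5	1e-03	B	ESR2-deficient pT1 breast tumor needing tamoxifen prophylaxis against cancer
ESR2	rs766797386	ttaaaaggaa	g	t	aaggggctta	6	7	↓	3	1e-02	C	(hypothetically) the same disease
HSD17B1	rs201739205	aggtgatatc	a	c	agcccagagc	13	18	↓	5	1e-06	A	higher risk of breast cancer
HSD17B1	rs201739205	agcaggtgat	a	t	tcaagcccag	13	35	↓	18	1e-06	A	(hypothetically) the same disease
HSD17B1	rs748743528	gcaggtgata	t	c	caagcccaga	13	28	↓	13	1e-06	A	(hypothetically) the same disease
HSD17B1	rs755636251	ggcgaagcag	g	t	tgatatcaag	13	11	↑	2	0.05	D	(hypothetically) higher risk of breast cancer
PGR	rs10895068	gggagataaa	g	a	gagccgcgtg	10	6	↑	8	1e-06	A	endometrial cancer caused by a spurious TATA box disbalancing progesterone-receptor isoforms
PGR	rs544843047	agtcgggaga	t	c	aaaggagccg	10	22	↓	14	1e-06	A	(hypothetically) health as the norm without the spurious TATA box
GSTM3	rs1332018	ccccttatgt	c	a	gggtataaag	4	3	=	2	1	E	maternal c allele elevates risk of brain tumor in child, renal cancer, Alzheimer's disease (TF site, not TATA box)
GSTM3	rs200209906	gtataaagcc	c	t,a	ctcccgctca	3.6	4.3	↓	2	1	E	(hypothetically) same disease; lower breast-cancer risk in never-drinkers	delta_at_alpha1
GSTM3	rs750789679	cgggtataaa	g	c	cccctcccgc	3.6	4.5	↓	3	1e-02	C	(hypothetically) same disease
GSTM3	rs748231432	cccttatgtc	g	c,t	ggtataaagc	3.6	3.0	↑	3	0.05	D	(hypothetically) lower risk of brain tumor in child of rs1332018 c-allele mother
GSTM3	rs763859166	gggtataaag	c	t	ccctcccgct	3.6	2.9	↑	3	1e-02	C	(hypothetically) lower risk of brain tumor in child of rs1332018 c-allele mother
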