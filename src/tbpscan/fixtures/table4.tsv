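gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
NOS2	-51t>c	gtataaatac	t	c	tcttggctgc	2	1	↑	3	1e-02	C	resistance to malaria and epilepsy; (hypothetically) higher risk of gestational diabetes mellitus
STAR	rs16887226	cagccttcag	c	t	gggggacatt	10	10	=	0	1	E	hypertensive diabetic patients (EMSA: unknown TF-binding site lost, not TATA box)
STAR	rs544850971	tcagcggggg	a	g	catttaagac	10	12	↓	5	1e-02	C	(hypothetically) lower risk of the same disease and congenital adrenal hyperplasia
APOA1	35a>c	tgcagacata	a	c	ataggccctg	3	4	↓	5	1e-06	A	fatty liver; (hypothetically) high risk of polycystic ovary syndrome in young women
CETP	DEL-51(18bp)	cgtgggggct	18bp	-	gggctccagg	4	7	↓	7	1e-06	A	hyperalphalipoproteinemia reducing risk of atherosclerosis
CETP	rs17231520	ggggctgggc	g	a	gacatacata	4	2	↑	10	1e-06	A	(hypothetically) biomarker of late pregnancy with raised plasma triglyceride, HDL, cholesterol
CETP	rs569033466	atacatatac	g	a	ggctccaggc	4	3	↑	4	1e-03	B	(hypothetically) biomarker of late pregnancy with raised plasma triglyceride, HDL, cholesterol
CETP	rs757176551	catatacggg	c	g	tccaggctga	4	2	↑	10	1e-06	A	(hypothetically) biomarker of late pregnancy with raised plasma triglyceride, HDL, cholesterol
SOD1	rs7277748	ggtctggcct	a	g	taaagtagtc	2	7	↓	17	1e-06	A	amyotrophic lateral sclerosis; (hypothetically) asthenospermia, lower female fertility via progesterone deficiency
TPI1	rs1800202	gcgctctata	t	g	aagtgggcag	1	4	↓	17	1e-06	B	hemolytic anemia, neuromuscular diseases; (hypothetically) higher risk of asthenospermia	rank_mismatch
TPI1	rs781835924	cgcggcgctc	t	c	atataagtgg	1	2	↓	10	1e-06	B	(hypothetically) higher risk of asthenospermia	rank_mismatch
GJA5	rs10465885	caactaagat	g	a	tattaaacac	3	3	=	1	1	E	arrhythmia, cardiovascular events (LUC: TF-binding site damaged, not TATA box)
GJA5	rs587745372	ggcgacagat	a	t	cgattaaaaa	6	7	↓	3	1e-03	B	(hypothetically) same disease and higher risk of heart morphogenesis disorders
GJA5	rs35594137	gaggagggaa	g	a	gcgacagata	6	6	=	0	1	E	arrhythmia, cardiovascular events (LUC: TF-binding site damaged, not TATA box)
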