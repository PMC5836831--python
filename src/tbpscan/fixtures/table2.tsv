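gene	variant_id	flank5	wt	mut	flank3	kd_wt_nM	kd_mut_nM	delta	z	alpha	rank	annotation	flags
IL1B	rs1143627	ttttgaaagc	c	t	ataaaaacag	5	2	↑	15	1e-06	A	high risks of gastric, liver, and non-small cell lung cancers; gastric ulcer; chronic gastritis; depression; obesity; Graves' disease; pre-eclampsia
IL1B	rs549858786	tgaaagccat	a	t	aaaacagcga	5	7	↓	8	1e-06	A	(hypothetically) lesser risk of the same diseases
CYP2A6	rs28399433	tcaggcagta	t	g	aaaggcaaac	2	9	↓	21	1e-06	A	low risk of lung cancer in smokers; (hypothetically) lesser damage from secondhand smoke in pregnant nonsmokers
CYP2A6	rs761592914	tttttcaggc	a	c	gtataaaggc	2	3	↓	3	1e-03	B	(hypothetically) the same disease
CYP2B6	rs34223104	gatgaaattt	t	c	ataacagggt	4	10	↓	15	1e-06	A	overexpression of bioactivator of immunosuppressive and antitumor prodrug cyclophosphamide	wt_merged_in_flank
CYP2B6	rs563558831	tgaaatttta	t	c	aacagggtgc	4	10	↓	13	1e-06	A	(hypothetically) the same problem
DHFR	rs10168	ctgcacaaat	g	a	gggacgaggg	15	9	↑	9	1e-06	A	resistance to methotrexate treatment of leukemia; (hypothetically) also in ectopic pregnancy, metastatic choriocarcinoma, gestational trophoblastic disease
DHFR	rs750793297	tgcacaaatg	g	t	ggacgagggg	15	13	↑	3	1e-02	C	(hypothetically) the same diseases
DHFR	rs766799008	ctgcacaaat	a	g	tggggacgag	15	19	↓	3	1e-03	B	(hypothetically) greater bioactivity of methotrexate during treatment
DHFR	rs764508464	ctgcacaaat	a	-	tggggacgag	15	37	↓	17	1e-06	A	(hypothetically) greater bioactivity of methotrexate during treatment
DHFR	rs754122321	ctcgcctgca	c	g	aaatggggac	15	25	↓	9	1e-03	B	(hypothetically) greater bioactivity of methotrexate during treatment
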