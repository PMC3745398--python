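study_id	first_author	year	ethnicity	design	control_source	genotyping_method	n_case	n_control	case_rr	case_rn	case_nn	ctrl_rr	ctrl_rn	ctrl_nn	raf_case	raf_control	stratum
stacey2008	Stacey	2008	European	GWAS	GP	SNP Array	4420	17365							0.54	0.50
milne2009	Milne	2009	European, Asian	GWAS	mixed	SNP Array, iPLEX	31511	35969							0.55	0.51
zheng2009	Zheng	2009	African	CandidateGene	GP	Massarray	810	1784							0.77	0.74
antoniou2009	Antoniou	2009	European, American	CandidateGene	GP	TaqMan, iPLEX	7805	6675							0.53	0.51
reeves2010	Reeves	2010	British	CandidateGene	GP	TaqMan	10306	10393							0.54	0.50
hemminki2010	Hemminki	2010	European	CandidateGene	GP	iPLEX	1415	1830							0.57	0.54
zheng2010	Zheng	2010	Chinese	CandidateGene	GP	SNP Array	3039	3082							0.11	0.11
barnholtzsloan2010	Barnholtz-Sloan	2010	American	CandidateGene	GP	GoldenGate	1230	1117							0.55	0.53
teraoka2011	Teraoka	2011	European, American	CandidateGene	GP	Golden Gate	704	1386							0.55	0.52
fletcher2011	Fletcher	2011	British	GWAS	GP	SNP Array, GoldenGate	7643	7443							0.53	0.52
campa2011	Campa	2011	American, European, African, Asian, Hawaiian	GWAS	GP	SNP Array, TaqMan	8314	11589							0.52	0.49
jiang2011	Jiang	2011	Chinese	CandidateGene	GP	SNaPshot	492	510							0.12	0.10
li2011	Li	2011	European	CandidateGene	GP	SNP Array	1557	4584							0.48	0.47
chen2011	Chen	2011	African	CandidateGene	GP	SNP Array	3016	2745							0.73	0.72
slattery2011	Slattery	2011	American	CandidateGene	GP	TaqMan	1733	2041							0.53	0.52
stevens2011	Stevens	2011	European, American, Australian	CandidateGene	GP	iPLEX	2977	4976							0.53	0.51
hutter2011	Hutter	2011	African	CandidateGene	GP	SNP Array	316	7484							0.69	0.70
dai2012	Dai	2012	Chinese	CandidateGene	GP	TaqMan	1771	1851							0.13	0.11
he2012	He	2012	European	CandidateGene	GP	TaqMan	3683	34174							0.55	0.50
shan2012	Shan	2012	Tunisian	CandidateGene	GP	TaqMan	640	367							0.58	0.55
kim2012	Kim	2012	Korean	GWAS	GP	SNP Array, TaqMan	2257	2052							0.10	0.10
huo2012	Huo	2012	African	CandidateGene	GP	GoldenGate	1509	1383							0.77	0.75
lin2012	Lin	2012	Chinese	CandidateGene	GP	SNP Array	88	69							0.15	0.06
harlid2012	Harlid	2012	European	CandidateGene	GP	MassARRAY	3393	4837							0.53	0.50
sueta2012	Sueta	2012	Japanese	CandidateGene	HP	TaqMan	697	1394							0.10	0.10
rinella2013	Rinella	2013	Jewish	CandidateGene	GP	KASPar	203	263							0.66	0.52
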