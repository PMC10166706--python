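ec_number	kegg_ids	role	stoich_weight	qpcr_marker	representative_genes	representative_enzymes
1.2.1.5	K00129	N	1.0	0	ALDH3	Aldehyde dehydrogenase (NAD(P)+)
1.2.7.7	K00187,K00188,K00186	N	1.0	0	vorB, vorD, vorA	2-Oxoisovalerate ferredoxin oxidoreductase beta subunit
1.3.1.95	K20143	N	1.0	0	acrC	Acrylyl-CoA reductase (NADH)
1.3.8.15	K24016	N	1.0	0	acdA	Cumarate reductase
2.3.1.109	K00673	N	1.0	1	yastA	Arginine N-succinyltransferase
2.3.1.9	K00626	N	1.0	0	ACAT, atoB	Acetyl-CoA C-acetyltransferase
2.6.1.19	K00823,K07250	N	1.0	1	ypuuE, gabT	4-Aminobutyrate aminotransferase, (S)-3-amino-2-methylpropionate transaminase, 5-aminovalerate transaminase
2.8.3.1	K01026	N	1.0	0	pct	Propionate CoA-transferase
2.8.3.18	K18118	D	1.0	1	yaarC, cat1	Succinyl-CoA:acetate CoA-transferase
3.5.1.107	K13995	D	1.0	0	nicF	Maleamate amidohydrolase
3.5.1.116	K18151	D	1.0	0	UAH	Ureidoglycolate amidohydrolase
3.5.1.54	K01457	D	1.0	0	atzF	Allophanate hydrolase
3.5.2.10	K01470	D	1.0	0		Creatinine amidohydrolase
3.5.2.15	K03383	D	1.0	0	atzD	Cyanuric acid amidohydrolase
3.5.3.12	K10536	D	1.0	1	yaguA	Agmatine deiminase
3.5.3.23	K01484	D	1.0	0	astB	Succinylarginine dihydrolase
3.5.3.9	K02083	D	1.0	0	allC	Allantoate deiminase
4.3.1.29	K17468	N	1.0	0	dgaE	D-glucosaminate-6-phosphate ammonia-lyase
4.4.1.15	K05396	D	1.0	0	dcyD	D-cysteine desulfhydrase
6.3.1.2	K01915	N	1.0	0	glnA, GLUL	Glutamine synthetase
6.3.4.6	K0194,K14541	N	1.0	0	dDUR1	Urea carboxylase, allophanate hydrolase
6.3.5.5	K01956,K01955,K11541,K11540	N	1.0	0	carA, CPA1, carB, CPA2, URA2, CAD	Carbamoyl-phosphate synthase, aspartate carbamoyltransferase, dihydroorotase
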