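# PKS/NRPS cluster inventory of Streptomyces lydicamycinicus TP-A0598 (= NBRC 110027).
# Locus tags carry the TPA0598_ prefix. Known products are recorded only for
# clusters identified by homology; orphan clusters have an empty known_product.
strain_id	cluster_id	ctype	known_product	locus_tag	size_aa	domain_organization	incomplete	assembly_order
TP-A0598	t1pks-1	t1pks		10_00280	2436	KS/AT/KR
TP-A0598	t1pks-1	t1pks		10_00270	1690	KS/AT/DH/ACP
TP-A0598	t1pks-2	t1pks		04_06320	444	KS
TP-A0598	t1pks-2	t1pks		04_06310	2113	KS/AT/DH/ER/KR/ACP
TP-A0598	t2pks-1	t2pks	Spore pigment	03_01500	422	KSa
TP-A0598	t2pks-1	t2pks	Spore pigment	03_01510	426	KSb(CLF)
TP-A0598	t2pks-1	t2pks	Spore pigment	03_01520	89	ACP
TP-A0598	t2pks-2	t2pks	Oxytetracycline	07_00590	425	KSa
TP-A0598	t2pks-2	t2pks	Oxytetracycline	07_00600	426	KSb(CLF)
TP-A0598	t2pks-2	t2pks	Oxytetracycline	07_00610	95	ACP
TP-A0598	t3pks-1	t3pks	THN	03_03810	353	KS
TP-A0598	nrps-1	nrps		07_04820	1066	C/A/T
TP-A0598	nrps-1	nrps		07_04810	641	A(leu)/T
TP-A0598	nrps-1	nrps		07_04800	637	A(val)/T
TP-A0598	nrps-1	nrps		07_04790	950	C/T
TP-A0598	nrps-2	nrps		02_01330	863	C/A/T
TP-A0598	nrps-2	nrps		02_01450	2734	A(asp)/T-C/A(asn)/T-C/A(leu)/T
TP-A0598	nrps-2	nrps		02_01460	2627	C/A(phe)/T-C/A(thr)/T/E
TP-A0598	nrps-2	nrps		02_01470	1883	C/T-C/A(leu)/T-TE
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00740	3598	KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00750	7054	KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00760	3548	KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00770	1846	KS/AT/DH/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00780	5648	KS/AT/DH/ER/KR/ACP-KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00790	3662	KS/AT/KR/ACP-KS/AT/DH/ER/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00800	3265	KS/AT/DH/KR/ACP-KS/AT/KR/ACP
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00820	1031	C/A/T
TP-A0598	pks/nrps-1	pks/nrps	lydicamycin, TPU-0037-A to -D	03_00840	1923	ACP-KS/AT/DH/KR/ACP
TP-A0598	pks/nrps-2	pks/nrps		08_01960	556	C/T		08_01890|08_01960|08_01950|08_01940
TP-A0598	pks/nrps-2	pks/nrps		08_01950	1139	T-C/A(val)/T
TP-A0598	pks/nrps-2	pks/nrps		08_01940	1207	KS/AT/ACP-TE
TP-A0598	pks/nrps-2	pks/nrps		08_01890	783	A(ser)/T
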