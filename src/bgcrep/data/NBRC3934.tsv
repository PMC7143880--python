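# PKS/NRPS cluster inventory of Streptomyces angustmyceticus NBRC 3934 (type strain).
# Locus tags carry the San01_ prefix; s*-* names are scaffold-derived identifiers for
# ORFs without assigned locus tags. incomplete=1 marks ORFs truncated at a scaffold
# terminus; size_aa values with a '>' prefix are lower bounds.
strain_id	cluster_id	ctype	known_product	locus_tag	size_aa	domain_organization	incomplete	assembly_order
NBRC3934	t1pks-1	t1pks		16600	2469	KS/AT/KR
NBRC3934	t1pks-1	t1pks		16610	1601	KS/AT/ACP
NBRC3934	t1pks-2	t1pks		20810	428	KS
NBRC3934	t1pks-2	t1pks		20820	2117	KS/AT/DH/ER/KR/ACP
NBRC3934	t1pks-3	t1pks	Trichostatin A	s29-1	>375	ACP/KS	1
NBRC3934	t1pks-3	t1pks	Trichostatin A	RS35710	>471	DH/ACP	1
NBRC3934	t1pks-3	t1pks	Trichostatin A	RS35715	>897	KS/AT	1
NBRC3934	t1pks-3	t1pks	Trichostatin A	RS31690	>1500	KS/AT/DH/KR/ACP	1
NBRC3934	t1pks-3	t1pks	Trichostatin A	64470	2005	KS/AT/DH/KR/ACP-TE
NBRC3934	t1pks-4	t1pks	Caniferolides	s04-1	>3397	KS/AT/ACP-KS/AT/KR/ACP-KS/AT	1
NBRC3934	t1pks-4	t1pks	Caniferolides	RS35695	>990	AT/KR/ACP	1
NBRC3934	t1pks-4	t1pks	Caniferolides	s40-2	>571	KS	1
NBRC3934	t1pks-4	t1pks	Caniferolides	RS35360	>4323	AT/KR/ACP-KS/AT/KR/ACP-KS/AT/DH/KR/ACP	1
NBRC3934	t1pks-4	t1pks	Caniferolides	71810	3953	KS/AT/DH/KR/ACP-KS/AT/DH/ER/KR/ACP
NBRC3934	t1pks-4	t1pks	Caniferolides	RS35370	>2135	KS/AT/KR/ACP-KS	1
NBRC3934	t1pks-4	t1pks	Caniferolides	RS35705	>1815	AT/DH/ER/DH/KR/ACP-KS	1
NBRC3934	t1pks-4	t1pks	Caniferolides	RS35690	>1167	AT/KR/ACP	1
NBRC3934	t1pks-4	t1pks	Caniferolides	s39-1	>577	KS	1
NBRC3934	t1pks-4	t1pks	Caniferolides	RS35595	>6115	AT/KR/ACP-KS/AT/KR/ACP-KS/AT/DH/ACP-KS/AT/KR/ACP-KS	1
NBRC3934	t1pks-4	t1pks	Caniferolides	RS31970	>1754	AT/DH/ER/KR/ACP	1
NBRC3934	t1pks-4	t1pks	Caniferolides	65020	5281	KS/AT/KR/ACP-KS/AT/DH/ER/KR/ACP-KS/AT/KR/ACP
NBRC3934	t1pks-4	t1pks	Caniferolides	65010	3643	KS/AT/KR/ACP-KS/AT/DH/KR/ACP-TE
NBRC3934	t1pks-4	t1pks	Caniferolides	64920	2404	CoL/T-KS/AT/DH/KR/ACP
NBRC3934	t2pks-1	t2pks	Spore pigment	26680	422	KSa
NBRC3934	t2pks-1	t2pks	Spore pigment	26670	416	KSb(CLF)
NBRC3934	t2pks-1	t2pks	Spore pigment	26660	96	ACP
NBRC3934	t2pks-3	t2pks	Trioxacarcin	00550	421	KSa
NBRC3934	t2pks-3	t2pks	Trioxacarcin	00560	417	KSb(CLF)
NBRC3934	t2pks-3	t2pks	Trioxacarcin	00570	89	ACP
NBRC3934	t2pks-3	t2pks	Trioxacarcin	00580	660	AT
NBRC3934	t3pks-1	t3pks	THN	24600	354	KS
NBRC3934	nrps-1	nrps		06160	1066	C/A/T
NBRC3934	nrps-1	nrps		06150	641	A(leu)/T
NBRC3934	nrps-1	nrps		06140	637	A(val)/T
NBRC3934	nrps-1	nrps		06130	950	C/T
NBRC3934	nrps-3	nrps		24170	6209	A(leu)/T-C/A(ala)/T/E-C/A/T/E-C/A(ala)/T/E-C/A(leu)/T
NBRC3934	nrps-3	nrps		24160	6677	C/A/T/E-C/A(thr)/T-C/A(orn)/T/E-C/A/T-C/A(leu)/T/E
NBRC3934	nrps-4	nrps		36160	3675	A/MT/T-C/A/T-C/A(gly)/T
NBRC3934	nrps-4	nrps		s07-1	>398	C	1
NBRC3934	nrps-5	nrps		27520	>3401	A(thr)/T-C/A(thr)/T-C/A/T-TE	1
NBRC3934	nrps-5	nrps		27580	591	A(arg)/T
NBRC3934	nrps-5	nrps		27590	1446	C/A(pro)/T-TD
NBRC3934	pks/nrps-3	pks/nrps	Guadinomine, partial	61570	252	KR
NBRC3934	pks/nrps-3	pks/nrps	Guadinomine, partial	61560	303	AT
NBRC3934	pks/nrps-3	pks/nrps	Guadinomine, partial	61550	302	AT
NBRC3934	pks/nrps-3	pks/nrps	Guadinomine, partial	61530	2393	A(pip)/T-KS/AT/DH/KR/ACP
NBRC3934	pks/nrps-3	pks/nrps	Guadinomine, partial	61520	270	TE
NBRC3934	pks/nrps-3	pks/nrps	Guadinomine, partial	61190	1178	A/T-TD
NBRC3934	pks/nrps-4	pks/nrps		12760	93	ACP		12780|12800|12760|12770|12810
NBRC3934	pks/nrps-4	pks/nrps		12770	674	KS/DH
NBRC3934	pks/nrps-4	pks/nrps		12780	526	A(ala)
NBRC3934	pks/nrps-4	pks/nrps		12800	1050	A/T(thr)-C
NBRC3934	pks/nrps-4	pks/nrps		12810	274	TE
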