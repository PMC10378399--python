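gene	chrom	pos	rsid	aa_change	workflow	discovery_families	subpop	maf	n_damaging	hope_size	hope_charge	cadd_ge20	gerp_positive	coseg_confirmed	additional_affected_ids	additional_unaffected_ids	extra_discovery_ids	unaffected_family_carriers	discovery_carrier_alleles	proband_alleles_total	ref_ac_override	reported_p	reported_verdict
PDHA2	4	1001	rs147966234	p.Arg286Pro	1	5463,5886	NFE	0.0089	5	decrease	pos_to_neu	yes	yes	yes	S01,A02	.	.	0	2	308	.	0.3590	P
PCDHB3	5	1002	rs61739886	p.Thr81Ile	1	4093,4130	NFE	0.0064	3	increase	none	yes	yes	yes	A03	.	.	0	2	308	.	0.5112	P
FURIN	15	1003	rs150925934	p.Arg462Trp	1	4075,5886	NFE	0.0017	4	increase	pos_to_neu	yes	yes	yes	.	.	.	0	2	308	.	0.06445	P
NOL6	9	1004	rs114465306	p.Pro134Leu	1	4130	NFE	0.00008	4	increase	none_reported	yes	yes	yes	A04	.	.	0	1	238	0	<0.0001	P
NOL6	9	1005	rs114110943	p.His366Tyr	1	5931	AFR	0.006	2	increase	none_reported	yes	yes	yes	.	.	.	0	1	308	.	NA	Likely P
IQGAP3	1	1006	rs147754283	p.Arg630Trp	1	4093	NFE	0.00005	3	increase	pos_to_neu	yes	yes	yes	.	.	.	0	1	308	.	NA	Likely P
IQGAP3	1	1007	rs112144116	p.Ala562Thr	1	5886	NFE	0.0034	4	increase	none	yes	yes	yes	A05,A06	.	.	0	1	308	.	0.1094	P
BAHCC1	17	1008	rs369588790	p.Arg2199Gln	1	4093	NFE	0.00006	2	none_reported	neg_to_neu	yes	yes	yes	.	.	.	0	1	308	.	NA	Likely P
BAHCC1	17	1009	rs200719992	p.Gln2463Glu	1	5931	AFR	0.0066	4	decrease	pos_to_neu	yes	yes	yes	.	.	.	0	1	308	.	NA	Likely P
GLI3	7	1010	rs35364414	p.Arg1537Cys	2	4093,4130,4132	NFE	0.0536	4	decrease	pos_to_neu	yes	yes	yes	S01,A07,A08,A09,A10,A11	U01,U02,U03,U04	.	0	3	308	.	0.7946	B
FLNB	3	1011	rs116826041	p.Ile2319Thr	2	4132	NFE	0.0093	3	decrease	none_reported	yes	yes	yes	A12,A13	.	M4299	1	1	308	.	0.3398	B
KMT2D	12	1012	rs146044282	p.Asp3419Gly	2	5463	NFE	0.0015	3	decrease	none_reported	yes	yes	yes	.	.	.	0	1	308	.	NA	Likely P
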