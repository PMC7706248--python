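# CAPS / Sanger validation of pooled-sequencing predictions in single plants.
# Published assay table: per-caller predicted VAF, observed allele frequency,
# number of plants genotyped, heterozygote count.  n_homalt is reconstructed
# as (round(vaf_obs*2n) - n_het)/2; NA where no integer count reproduces the
# printed observed frequency.  recovered = variant seen in at least one plant.
gene	pos	ref	alt	method	enzyme	accession	vaf_gatk	vaf_snver	vaf_crisp	vaf_obs	n_plants	n_het	n_homalt
MATE1	170	A	G	CAPS	NotI	D2	0.880	0.587	0.819	0.79	26	11	15
MATE1	170	A	G	CAPS	NotI	E12	0.875	0.592	0.783	0.70	27	8	15
MATE1	210	A	G	CAPS	TaqI	H5	0.172	0.079	0.276	0.38	25	15	2
MATE1	364	G	C	CAPS	MboI	H5	0.307	0.137	0.393	0.24	25	8	2
PBF	310	C	T	CAPS	MnlI	D2	0.292	0.206	0.165	0.44	25	14	4
PBF	310	C	T	CAPS	MnlI	E12	0.120	0.059	0.059	0.10	25	5	0
PBF	517	G	A	CAPS	MboI	D2	0.286	0.262	0.180	0.44	27	12	6
PBF	517	G	A	CAPS	MboI	E12	0.016	0.104	0.065	0.09	27	5	0
PBF	532	C	T	CAPS	FokI	D2	0.104	0.096	0.138	0.00	26	0	0
PBF	532	C	T	CAPS	FokI	E12	0.536	0.405	0.472	0.43	25	14	NA
PBF	666	C	T	Sanger	NA	F8	0.401	0.371	0.359	0.58	25	11	9
PBF	810	C	T	Sanger	NA	F10	0.042	0.022	0.068	0.00	6	0	0
PBF	810	C	T	Sanger	NA	F11	0.214	0.074	0.216	0.16	16	5	0
PBF	846	G	C	Sanger	NA	F8	0.094	0.053	0.104	0.10	25	5	0
PBF	847	G	A	Sanger	NA	F8	0.094	0.064	0.100	0.08	25	4	0
Sinb	211	A	G	CAPS	FokI	H5	0.026	0.183	0.111	0.00	25	0	0
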