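phage	accession	cluster	host	host_clade	genome_size_bp	n_orfs	gc_percent
P-RSP2	HQ332139	outlier	Prochlorococcus	HLII	42257	48	34.0
P60	AF338467	MPP-A	Synechococcus	5.1-VI	46675	55	53.3
Syn5	EF372997	MPP-A	Synechococcus	5.1-II	46214	61	55.0
P-SSP9	HQ316584	MPP-A	Prochlorococcus	LLII	46997	54	40.5
S-CBP2	KC310806	MPP-A	Synechococcus	5.2-CB4	46237	53	55.0
S-CBP42	KC310805	MPP-A	Synechococcus	5.1-V	45218	57	54.6
P-SSP7	AY939843	MPP-B	Prochlorococcus	HLI	44970	54	38.8
P-SSP5	GU071100	MPP-B	Prochlorococcus	HLI	47055	55	39.2
P-RSP5	GU071102	MPP-B	Prochlorococcus	LLI	47741	68	38.7
P-HP1	GU071104	MPP-B	Prochlorococcus	LLI	47536	66	39.9
P-SSP2	GU071107	MPP-B	Prochlorococcus	HLII	45890	59	37.9
P-GSP1	HQ332140	MPP-B	Prochlorococcus	HLI	44945	53	39.6
P-SSP3	HQ332137	MPP-B	Prochlorococcus	HLII	46198	56	37.9
P-SSP10	HQ337022	MPP-B	Prochlorococcus	LLI	47325	52	39.2
P-SSP11	HQ634152	MPP-B	Prochlorococcus	HLI	47039	54	39.2
S-CBP1	KC310802	MPP-B	Synechococcus	5.2-CB4	46547	51	47.6
S-CBP3	KC310803	MPP-B	Synechococcus	5.2-CB4	45871	55	47.0
S-CBP4	KC310804	MPP-B	Synechococcus	5.2-CB4	44147	49	44.4
S-RIP1	HQ317388	MPP-B	Synechococcus	5.1-VIII	44892	54	42.9
S-RIP2	HQ317389	MPP-B	Synechococcus	5.1-V	45728	56	47.3
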