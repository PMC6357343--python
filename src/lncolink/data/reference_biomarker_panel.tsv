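mrna_id	gene_symbol	mrna_direction	mrna_q	lnc_id	relationship	lnc_direction	lnc_q
NM_000787	DBH	down	0.0153	ASHG19A3A038177	natural antisense	down	0.0317
NM_015987	HEBP1	down	0.0153	ASHG19A3A048399	bidirectional	down	0.0252
NM_001172440	ENDOU	down	0.0161	ASHG19A3A055103	intronic antisense	down	0.0285
NM_001130997	FAM58A	up	0.0170	ASHG19A3A041726	bidirectional	up	0.0331
NM_000075	CDK4	up	0.0216	ASHG19A3A048765	natural antisense	up	0.0396
NM_000744	CHRNA4	down	0.0218	ASHG19A3A018571	intronic antisense	down	0.0285
NM_003074	SMARCC1	up	0.0231	ASHG19A3A022584	intronic antisense	up	0.0285
NM_025139	ARMC9	up	0.0240	ASHG19A3L0001156	sense overlap	up	0.0472
NM_014053	FLVCR1	up	0.0270	ASHG19A3A007495	bidirectional	up	0.0479
NM_000348	SRD5A2	down	0.0271	ASHG19A3L0001181	exon sense-overlapping	down	0.0357
NM_001012321	RPSA	up	0.0279	ASHG19A3A020907	natural antisense	down	0.0293
NM_001334	CTSO	down	0.0284	ASHG19A3A026206	natural antisense	down	0.0415
NM_030789	HM13	up	0.0284	ASHG19A3A017537	intronic antisense	down	0.0479
NM_000454	SOD1	down	0.0311	ASHG19A3A018779	bidirectional	down	0.0468
NM_002394	SLC3A2	up	0.0314	ASHG19A3A000043	bidirectional	up	0.0291
NM_144778	MBNL2	down	0.0315	ASHG19A3L0000699	exon sense-overlapping	down	0.0439
NM_001146279	SHBG	down	0.0315	ASHG19A3A007528	exon sense-overlapping	down	0.0380
NM_003631	PARG	up	0.0328	ASHG19A3A043936	intronic antisense	up	0.0289
NM_000182	HADHA	down	0.0330	ASHG19A3A015417	natural antisense	up	0.0489
NM_003668	MAPKAPK5	up	0.0333	ASHG19A3A055106	natural antisense	up	0.0364
NM_016065	MRPS16	up	0.0338	ASHG19A3A044109	bidirectional	up	0.0362
NM_053031	MYLK	down	0.0338	ASHG19A3A023105	intronic antisense	up	0.0285
NM_001040058	SPP1	up	0.0355	ASHG19A3A024471	natural antisense	up	0.0356
NM_145697	NUF2	up	0.0355	ASHG19A3A054586	bidirectional	up	0.0412
NM_172250	MMAA	down	0.0372	ASHG19A3A024820	natural antisense	down	0.0409
NM_001003789	RABL2B	down	0.0378	ASHG19A3A020631	bidirectional	up	0.0252
NM_001040060	SPP1	up	0.0378	ASHG19A3A024471	natural antisense	up	0.0356
NM_207304	MBNL2	down	0.0379	ASHG19A3L0000699	exon sense-overlapping	down	0.0439
NM_020791	TAOK1	up	0.0382	ASHG19A3A009329	exon sense-overlapping	up	0.0412
NM_016632	ARL17A	up	0.0395	ASHG19A3A008470	intron sense-overlapping	up	0.0252
NM_014583	LMCD1	up	0.0397	ASHG19A3A020672	bidirectional	down	0.0311
NM_003937	KYNU	down	0.0405	ASHG19A3A014435	natural antisense	down	0.0252
NM_000582	SPP1	up	0.0418	ASHG19A3A024471	natural antisense	up	0.0356
NM_014389	PELP1	up	0.0419	ASHG19A3A008987	natural antisense	up	0.0437
NM_148921	EPN2	down	0.0433	ASHG19A3A008042	natural antisense	up	0.0329
NM_001165031	DTYMK	up	0.0442	ASHG19A3A007748	exon sense-overlapping	up	0.0285
NM_002482	NASP	up	0.0448	ASHG19A3A044925	natural antisense	up	0.0489
NM_000128	F11	down	0.0449	ASHG19A3A025095	natural antisense	down	0.0252
NM_002022	FMO4	down	0.0468	ASHG19A3A034907	intron sense-overlapping	down	0.0446
NM_001127603	NMRK1	down	0.0470	ASHG19A3A037588	exon sense-overlapping	down	0.0331
NM_003889	NR1I2	down	0.0471	ASHG19A3A021464	natural antisense	down	0.0291
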