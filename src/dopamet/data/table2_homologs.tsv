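gene_id	homolog_symbol	homolog_accession
08j13		no homolog
08b22	HSD17B12	NM_016142
16j14	PSMC1	NM_002802
08e14	RPS27	NM_001030
07f01	ABHD12	NM_001042472
22n08	AK3	NM_016282
08k20	ALDH7A1	NM_001182
03h23	ALDOC	NM_005165
05f06	A2M	NM_000014
22i24	ACTA1	NM_001100
09p02	AGT	NM_000029
09j02	APOA4	NM_000482
16n14	APOE	NM_000041
04a17	CYP19A1	NM_000103
14k14	ACTR2	NM_005722
12l13	ASF1B	NM_018154
16l15	ABCF2	NM_007189
16o14	BLCAP	NM_006698
03o22	ACTB	NM_001101
22l24	BCKDK	NM_005881
02a23		no homolog
14g01	CLDN23	NM_194284
14k02	CCDC47	NM_020198
19a04	CSDE1	NM_001007553
08o15	C3	NM_000064
08b20	C1QL4	NM_001008223
02c23	CKB	NM_001823
02n10	CKM	NM_001824
21l19		no homolog
19a14	CUBN	NM_001081
17g09	CXXC1	NM_001101654
06d13	CYP2F2	NM_007817
05l01	CIAPIN1	NM_020313
03f23	DNASE1L3	NM_004944
23k24	WWP1	NM_007013
02i24	EPDR1	NM_017549
03o21	EPDR1	NM_017549
24a12	EPHA7	NM_004440
15a10	SLC29A1	NM_001078174
07b01	EEF1G	NM_001404
20j14	EIF2S1	NM_004094
09e01	FN1	NM_212482
24j21	FKBP1A	NM_054014
03o09	ALDOC	NM_005165
10m11	GGCT	NM_024051
17n11	GGCT	NM_024051
03i20	GLUL	NM_001033044
10d04	GPX3	NM_002084
23o12	GAPDH	NM_002046
08h01	GNPAT	NM_014236
14b13	GRN	NM_002087
19m14	H2AFY2	NM_018649
14k03	HSP90AB1	NM_007355
14i04	HECTD1	NM_015382
24o12	HK1	NM_000188
08g14	HDLBP	NM_005336
19d02	HSD17B10	NM_001037811
03i10	LOC100510678	XM_003120441
04j23	KDM6B	NM_001080424
13o14	LXN	NM_020169
22g07	LRRFIP1	NM_001137550
11p01	LRRC58	NM_001099678
19f13		unknown
14m01	MDH1	NM_005917
12k14	MSL1	NM_001012241
22o11	MARK4	NM_031417
21l16	MPP1	NM_002436
09p22	MCCC2	NM_022132
22k08		unknown
08a03	MID1IP1	NM_021242
09k02	MID1IP1	NM_021242
08l01	FTH1	NM_002032
03k10		no homolog
12n01	MRPL19	NM_014763
19p16	MRPL20	NM_017971
11j11	MAP3K7	NM_003188
12p13	MPHOSPH6	NM_005792
06g06	MYC	NM_002467
14n02	MYLPF	NM_013292
24b19	NCK2	NM_003581
19l18	TH1L	NM_198976
03i12	NELL2	NM_001145107
16k15	NLRC3	NM_178844
18c18	NSUN2	NM_017755
08o01		no homolog
11d07		no homolog
15i06		no homolog
15b13	LMO3	NM_001001395
11e15	SULT1A1	NM_001055
19e01	NR1D2	NM_005126
15e23	PDCL3	NM_024065
12l11	RBP4	NM_006744
03k09		no homolog
08g04	PTGDS	NM_000954
22p03	PSMD4	NM_002810
12b01	PSMA5	NM_002790
12i01	PNP	NM_000270
22b23	C13orf15	NM_014059
22g21	RPL13	NM_000977
08o16	RPL27A	NM_000990
12d13	RPL27A	NM_000990
09o01	SERINC1	NM_020755
21a01	SH3GL1	NM_003025
09g14		no homolog
24i19	STARD4	NM_139164
09n02	SC5DL	NM_006918
12p21	SURF4	NM_033161
20o02	TSPAN9	NM_006675
24i22	TALDO1	NM_006755
15f10	SSR4	NM_006280
12f01	TTR	NM_000371
07h01	TPI1	NM_000365
14f24	TNNC2	NM_003279
21g17	TNNC2	NM_003279
22g09	TUBA1B	NM_006082
03o23	TUBB2C	NM_006088
17j23	TUBB2C	NM_006088
14f02	U2AF1	NM_006758
22l09	VPS13C	NM_018080
20j02	VPS4A	NM_013245
14j12	VIM	NM_003380
24i24	VIM	NM_003380
12i13		no homolog
19o08	DPF2	NM_006268
23a24	ZC3H7B	NM_017590
15i14	ZNF782	NM_001001662
20c13		no homolog
12o17	CEBPB	NM_005194
12e10	LRPPRC	NM_133259
14f04	SLC2A7	NM_207420
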