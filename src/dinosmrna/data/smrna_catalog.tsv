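id	smrna_class	sequence	length	stemloop_len	mfe_kcal_mol	mature_reads	star_reads	star_conditions
smb107.2	miRNA	CAAGGAUGGGAUGCUCAGAGAA	22	88	-69.3	13315	398	9
smb107.3	miRNA	CAAGGAUGGGAUGGUCAGAGAA	22	88	-64.1	3322	398	9
smb123	miRNA	CAGUCGGCCAAAGUGCUGGACC	22	89	-64.1	451	154	9
smb203	miRNA	CUUUGUAUCCCGGAUCCUGAUA	22	87	-46.6	1087	389	9
smb215	miRNA	GAGGAUGCUGAUCAUUCACUGG	22	87	-80.6	85	34	8
smb295	miRNA	UCAGAGACCAGACGCAGAGGCU	22	90	-40.6	12543	160	9
smb297	miRNA	UCAGUGGCAGAAGCUGGGAACU	22	87	-63.5	965	60	8
smb313	miRNA	UCGAACUUUCAGGAAUAGUAUC	22	87	-54.8	2707	1475	9
smb21	siRNA	AAUUUGAACGUUGCCAUCUAUC	22	87	-72.5	123	9	7
smb41	siRNA	ACCUGCAGCAUUUGGCGCCUGA	22	84	-77.9	299	18	7
smb51	siRNA	ACUUAGAACUCUCCUACGAGGG	22	88	-83.1	510	275	8
smb79	siRNA	AGUUGGACCAGACCAGUUGGUC	22	87	-71.7	489	319	9
smb83	siRNA	AUCACUCCACAAAGGGAUUUG	21	87	-65.5	217	7	5
smb101	siRNA	CAACGAGAUUGGCCUUCUGUGC	22	87	-82.9	5234	412	9
smb163	siRNA	CGGGACUCGAUUCGGAGGGUGC	22	88	-63.6	2015	660	9
smb271	siRNA	UAGAAUGUAGUCGUCAUCUUGC	22	88	-68.9	1044	29	9
smb303	siRNA	UCCGCCGUGCAACUGUCGCAAC	22	88	-80.2	207	107	9
smb359	siRNA	UGAUGUACAUCGAUUGAUCGAC	22	86	-63.8	646	23	9
smb365	siRNA	UGCCAACGUGAUUUGCAACUCC	22	84	-68.1	333	75	7
smb379	siRNA	UGGACUUGGAAAGCUUCUCUGC	22	86	-76.7	2505	2	2
smb427	siRNA	UUUGUCCAGUGUACCUGCGCU	21	85	-73	728	50	8
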