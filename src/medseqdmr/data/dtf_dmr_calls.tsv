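# description=Published DMR calls (fold change >= 1.5, sex chromosomes excluded) from the desmoid-type fibromatosis CTNNB1 S45F vs T41A MeD-seq comparison; hg38, positions 1-based inclusive. Transcribed verbatim, including one record with a missing fold change and one with reversed start/end coordinates.
# min_fold_change=1.5
chromosome	fold_change	start	end	status_S45F	status_T41A	overlapping_genes	position_label
19	2.68	55850028	55850071	+	-	NLRP4	postTSS1KB-TES
17_GL383563v3_alt	2.27	130411	131133	-	+
17	1.85	82585430	82587461	-	+	FOXK2	postTSS1KB-TES
16	1.79	85410202	85410284	+	-
1	1.77	977947	977974	-	+	PERM1	postTSS1KB-TES
21		42956670	42958541	+	-
10	1.70	59882022	59883084	-	+	CCDC6	postTSS1KB-TES
10	1.69	42089321	42090999	+	-
12	1.65	132149685	132150607	+	-	NOC4L	postTSS1KB-TES
4	1.50	190075267	133745860	+	-	DUX4L6	TSS
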