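dataset	context	pred_clique	pred_gibbs	printed_clique	printed_gibbs
1	GAAACCctgtta	AAACCC	GAAACC	0.83	1.00
1	GAAGCCcttcaa	AAGCCC	GAAGCC	0.83	1.00
1	GAAGCCgcaaaa	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCcctcac	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCaattat	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCttagaa	GAAGCC	GAAGCC	1.00	1.00
1	GAATCCttagat	GAATCC	GAATCC	1.00	1.00
1	GAAACCttgcaa	GAAACC	GAAACC	1.00	1.00
1	GAAGCCaatcat	GAAGCC	GAAGCC	1.00	1.00
1	GAAACCttatga	GAAACC	GAAACC	1.00	1.00
1	GAAACCtttcaa	GAAACC	GAAACC	1.00	1.00
1	GAAACCatagac	GAAACC	GAAACC	1.00	1.00
1	GAAGCCttatta	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCcccaaa	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCgtagct	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCacaatt	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCgtgttt	GAAGCC	GAAGCC	1.00	1.00
1	GAAACCttatct	GAAACC	GAAACC	1.00	1.00
1	GAAGCCgtacaa	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCtacaaa	GAAGCC	GAAGCC	1.00	1.00
1	GAAACCttattt	GAAACC	GAAACC	1.00	1.00
1	GAAGCCgtaaaa	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCAccttat	AAGCAC	GAAGCA	0.83	1.00
1	GAAGCCttaaaa	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCgtagat	GAAGCC	GAAGCC	1.00	1.00
1	GAAGCCactttt	GAAGCC	GAAGCC	1.00	1.00
1	GAATCCctacaa	GAATCC	GAATCC	1.00	1.00
2	tgaatacCACGTG	CACGTG	CACGTG	1.00	1.00
2	gggatCACGTGgt	CACGTG	CACGTG	1.00	1.00
2	attgtgCACGTGg	CACGTG	CACGTG	1.00	1.00
2	CACGTGggaggtac	CACGTG	CACGTG	1.00	1.00
2	gggtCACGTGttc	CACGTG	CACGTG	1.00	1.00
2	taagCACGTGgtc	CACGTG	CACGTG	1.00	1.00
2	CACGTGccgcgcgc	CACGTG	CACGTG	1.00	1.00
2	aggtataCACGTG	TACACG	CACGTG	0.67	1.00
2	AACGTGcacatcgtcc	AACGTG	CACGTT	1.00	0.00
2	AACGTGacttcgtacc	AACGTG	CACGTT	1.00	0.00
2	CACGTGatgtcctc	CACGTG	CACGTG	1.00	1.00
2	CACGTGaagttgtc	CACGTG	CACGTG	1.00	1.00
2	AACGTGacagccctcc	AACGTG	CACGTT	1.00	1.00
2	agtCACGTGttcc	CACGTG	CACGTG	1.00	1.00
2	taaatgcCACGTG	CACGTG	CACGTG	1.00	1.00
2	tgaCACGTGtccg	CACGTG	CACGTG	1.00	1.00
2	AACGTGcgtgatgtcc	AACGTG	CACGTT	1.00	0.00
2	catgtCACGTGcc	CATGTC	CACGTG	0.17	1.00
2	aggaatCGCGTGc	CGCGTG	Not Found	1.00	0.00
2	agttcgCACGTGc	CGCACG	CACGTG	0.67	1.00
3	gcacATAGGTGTAAAatggccgttgg	CATAGGTGTAA	CACATAGGTGTAA	0.91	0.73
3	ctcgcacCCAGGTGTGAAgttctggt	CCCAGGTGTGA	CACCTGGGTGCGA	0.91	0.00
3	acGTAGGTGCGAAtctatcttagtgc	CGTAGGTGCGA	Not Found	0.91	0.00
3	gcgagatgtaacatGTAGGTGTGAAa	TGTAGGTGTGA	CATGTAGGTGTGA	0.91	0.73
3	ctttactcacCTAGGTGTGAAtgaag	CCTAGGTGTGA	CACCTAGGTGTGA	0.91	0.73
3	gcacGTAGGTGCTACttttttgtaa	CGTAGGTGCTA	CACGTAGGTGCTA	0.91	0.73
3	acatagtgacacCTAGGTGTGAAatt	CCTAGGTGTGA	CACCTAGGTGTCA	0.91	0.73
3	cgtcacgcGTAGGTGTTACaatgtgg	CGTAGGTGTTA	CGCGTAGGTGTTA	0.91	0.00
3	gtcatGTAGGTGTGAAtatagcgccc	TGTAGGTGTGA	CATGTAGGTGTGA	0.91	0.73
3	tttgacacCTAGGTGTCATattccac	CCTAGGTGTCA	CACCTAGGTGTCA	0.91	0.73
3	tatcgcacCTAGGTGTGACaatcatc	CCTAGGTGTGA	CACCTAGGTGTGA	0.91	0.73
3	gcaaGTAGGTGTGAAatctcaacgga	AGTAGGTGTGA	CAAGTAGGTGTGA	0.91	0.73
3	acatagtgacacCTAGGTGTGAAattc	CCTAGGTGTGA	CACCTAGGTGTCA	0.91	0.73
3	gtggaatatgacacCTAGGTGTCAAa	CCTAGGTGTCA	CACCTAGGTGTCA	0.91	0.73
3	acacCTAGGTGTGAAattcagatata	CCTAGGTGTGA	CACCTAGGTGTGA	0.91	0.73
3	attagtcacacCTAGGTGTGAAgagc	CCTAGGTGTGA	CACCTAGGTGTGA	0.91	0.73
3	ccagtatcacacTTAGGTGTTACatc	CTTAGGTGTTA	CACTTAGGTGTTA	0.91	0.73
3	tctactaacagGTAGGTGTTACttgt	GGTAGGTGTTA	CAGGTAGGTGTTA	0.91	0.73
3	gcggAAAGGTGTGAAatcacaccatt	GAAAGGTGTGA	Not Found	0.91	0.00
3	gaattcacacTTAGGTGTGAAat	CTTAGGTGTGA	CACTTAGGTGTGA	0.91	0.73
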