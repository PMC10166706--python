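ec_number	pair_id	forward	reverse
2.3.1.109	Rxn1_1	CGGTGCTGGAGAAAGAAGGT	CAGTTGTGCGGCGGTTAAAA
2.3.1.109	Rxn1_2	GATTTTAGCCGCGCCGATTT	TACCTGACCGATGACGTCCT
2.3.1.109	Rxn1_3	TGAGCTTTGCACGCTGTTTC	GTTTGCCGAGACTTTGCCAG
2.3.1.109	Rxn1_4	TGGTACAACTATCGCGTCGG	GTCCAGGAACAGCGTACACA
2.6.1.19	Rxn2_1	AGAAAGCCAACGATCTGGGG	CGCAGCACGTTGTAATACGG
2.6.1.19	Rxn2_2	GTCATGTTTATCGCGCGCTT	TGATGGCGGCGATATCTTCC
2.6.1.19	Rxn2_3	AGACGGATTGCTGGCGATAG	CGCAGCACGTTGTAATACGG
2.6.1.19	Rxn2_4	TGAAGACGGCGATCACAACA	CGCAGCACGTTGTAATACGG
3.5.3.12	Rxn3_1	CCTCGTGATTTTGGGGCTGA	GCCATCATAATGCCATCGCC
3.5.3.12	Rxn3_2	ATCCGTGGTGTGGATTGGAC	CTACGTGGAATGAACCGCCT
3.5.3.12	Rxn3_3	CTGGGGATTGAAGTTCGCCT	AGGCATTCGGTGGTGGTAAG
3.5.3.12	Rxn3_4	GCCCGCTACCTACGCTAATT	CATCGTTACGCAATGCAGGG
2.8.3.18	Rxn4_1	CAGTGCACAAGAAGCTGCTG	CGTTCAGCAAGAGCCAAAGG
2.8.3.18	Rxn4_2	TACCTGGGGAAGATCGACGT	ATCTCAATGGCCTGGGTGTG
2.8.3.18	Rxn4_3	CGCATCTACCGCTCCTGATT	GAAGCCCTCTTCAACCTGCT
2.8.3.18	Rxn4_4	TAACTGCGCACACCCTGATT	ACAGCATAGTGCCGGTTTCA
16S	U16s	GTGSTGCAYGGYTGTCGTCA	ACGTCRTCCMCACCTTCCTC
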