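locus	gene_length	fwd_primer	rev_primer	amplicon_size	fragment_start	fragment_end	fragment_size	n_genotypes	n_variable_sites	n_nonsynonymous	n_synonymous
IPP1	864	ATCGGTGCCAAGAACACCTT	TTGTCGATTGGCTCGTCTGG	803	44	806	763	28	25	4	21
TFC1	1857	AAGGCCGATTTGGGTCAAAC	TCTGCGGACTCAGAGTTATGC	832	992	1782	791	37	44	19	25
GPH1	2712	TGGAACACTGTGAAGCAGCA	TTTCGTCAGCGTACTCCTGG	902	1797	2658	862	30	34	8	26
GSY2	2106	CACGCCATGAGATTCCCTCA	CGTCCTCTTCGTCGTCATCC	891	1197	2067	871	34	49	19	30
SGA1	1788	CTCCGATGGTTCGGGTCAAT	TCATGGGTCAAGGTACTGGC	926	179	1084	906	26	44	13	31
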