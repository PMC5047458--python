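id	forward	reverse	annealing_c	products
1	CAGGGCAGCCAGCCTCGCCGCCTGTTGTG	ATGGGAGGGTAGGAGGTGGTGTTCTTCAC	62	208
2	GCGATGCCCCAGAAGAGGAGGTCAGT	CAGCTCAGCATGCTTTATCTTGGGTG	62	534
3	GAACCCCAATGGGGAGGGGCTGCCCC	CAGCTCAGCATGCTTTATCTTGGGTG	62	181
4	TACCGCCTGGGCATCTGGGGATTCTTCAG	AGTTGCCCCGGCTGTGTTCATCCCCTGTG	62	2327/3811
5	CAGCAGGAGGGGAAAGTGTCTCTGTTCTG	AAGAGGTTCTTGGCCAAGGGAGACAACAC	62	1540/3558
6	TCAGGAAGGACATGAAGGCTGCAGCTAAG	GTTTTACACCCAGCAAGGACAGCAATTTG	62	1869/1213
7	ACGAGCTCTTGGACTTAACGCTGAAGATG	TCTCCATGCAAATCAAGAGTTAAAGGTTT	62	2287/4056
8	ATCTGTGACGGTGGCCCGTCAACACAGAG	CTCATACATGTAGGTGGGGGCTCCTGCAT	62	3919/4758
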