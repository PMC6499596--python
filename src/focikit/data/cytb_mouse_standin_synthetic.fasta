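>synthetic_mouse_cytb_standin length-calibrated synthetic stand-in (NOT the authentic mouse mitochondrial Cytb sequence); expected product 196 nt
GCAGGACGAAGTGTCCTTGAACCATGTTCGCGGCGATTTATTTGTTGGGTCTCCTCTGTCTCCAGCTCAC
TAAAATGAGATATTTATATAATTGTTTATTGATTGTGGTTGCTTTAGAAGACACGAGCAGTTCTGTAGAG
TAATTGTTAAAGTCGGTGAATGAGATAGCCGCCTCTCGTACCTCAAAGCAACGAAGCCTAGACAATTGCA
TTCTACCAGAGTCAGGAGTTCATTCCTGTAGCGGTACGAATTTTATCTCCCTAAGCCTCGCTCCCCCGCC
GGCACGCGTTGGCCGAAGGACCCACGCTACACCCGGGGGTCACGTGACACTGATGGCGTAAGCTCAGGTT
GGGCCAATCTCAGGAATTATCGAAGATTGGGCGAAGCCTGCGCAAGAATCCGACAAATTCCGTCGCTCTG
ATTTAGCTAACAGAAACTGCGAGAGGTCTCTTCAAACTGCAAGGCATGGTAGCTATGCCGGCCCAGCATA
CGGCACATACTGCGAGGTGGGATCAGAGTCGTGCGCTAGCGGCCCGTCGTTCCAATGCTTGAAAAT
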