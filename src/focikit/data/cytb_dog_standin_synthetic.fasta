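>synthetic_dog_cytb_standin length-calibrated synthetic stand-in (NOT the authentic dog mitochondrial Cytb sequence); expected product 247 nt
GACCAATTAAGTGGGCATAAATATTGTGAAAGCTATTTAAGTGAGGACTTACAACATCGCCCAGGCCCGC
TCTGCTGGTTGCGCCACCCGGGCAGAGCCCTCCAGTCCACATCGATTGTCAACGGCTAGTTAAGTACCTC
TTATGCCGATCTACATGGCACCGGGGGGCCGTGACTAGACCATAGCCACAGCATTCATGGCATAGTATAT
ATACGATCCAACGTGAGTGGGTGCAAAACATAGGCATTCTATGGGCGCCAGTATTGGATCTGAGAAGCCG
CGCAAAGAGCCAACTTTTTACCTCGCTGCGCCACGACGTTCGACCTAGCAATGGGGCGCGTTCGTCAGAT
GAGTGCTCCTAGCTTTAGTGTTAGGGATATCGCGCTTTATTTCGCAGGTCAGTCGTATTCTACACGAAAC
CGGATCCCCCCCCTTCAGGTACGCAACTCTGCTCCACATATACTACCTTCATCAGGAGAGGAAATTCGTA
CTTGAACAAAGGCACGTTTTGACCTGATAACTGCCATCCTTTTCTCAGTCTGGCGGCGATACTCTTGCAA
AGTGGTCTGATAACGCACTAAGGCTTGTCGGAATCTGTGTACATAGC
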