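>SVA_consensus_synthetic synthetic stand-in SVA consensus (hexamer 1-72, Alu-like body from 73, poly-A tail)
CCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCTCTCCCT
CTAATTATGTGTAGAATTTCACTAATACTTCAACGGCGTTGCATGCTCATTACAAACTACCGCTATAGTG
AACGCGCGATTGGCATCAATTTTCGGTCGGTATAATTGGGTAGCGCGGAGGTTGGTATTGTAATCTGTCT
GCCGTGTTCACTTCACGGCGACCTGACAGTGCAACTCCACGGTCCACGTTTTCTCACTCTATACAGAGGT
AACTAAGAAGGGTAAGATAATGGAGTCGTAGGTGGATTCAGCACTACATAACTCTGGAAGTCCGTTCCAT
CACTAGCTTAGCTTACGGTAATTTACCAGTGCCCAGTTGACCGACGGTCTGGGTACTTACGAGGTTCTCT
AATCAATCCTTATTATGTGTCGCCACCGGCGCTTATGAACAGCGGTCTTGTCTAGCATGAAGGTTCTGTA
GTCTACGTCCAAGATATTTGGGGGCCCCAGGACTTGCGTACTCATATAGCACTTTCCTACCAAGGTGCTT
TTTGACTCGGTTAATACTTTTGATTAGCTGCGCGCACGACGCCTTATGCTAGAGGTTTTAATGGAAACGT
TTTACGCACGTAACGCAGGAATCGTGGGCTGGCCCAATACCTCTAGCGGCTTTCCTGACACATTGCGTTT
TCTAACCACTGCCGTATACAAGACATCCGGAGCGGTTGTCTAGCTATGTACGGGTGCAGATGCACAGTGA
TTGGTAGACCAAGGCTACAACCGCGCAAATACGTGTTTGTTCCGCGAGCCAACACGGCGCCCTGGGGAGG
CCTAGGATGCACCTTCATTGCCCGGGGACCACATATTGCGCGGATCTCAAAATATCCCGTGTTTGGCGCT
GGATAAGAATAGCGTGCTAGGACTGCGGGCAATTTGAGGAGAACGAAACAGAAGCCTCGTTTCACGTCGG
CCGAACCGACCACGAATGATAAAATGTATAAGACCTTTTGAAAGCTCCGGTTTCAGCCGCAACAGCCCTG
TTACATCGATATTCAATAAATTGGACGGTTCACTGGATGCTTGCATAGCCCAGAGTAACGCCTTATGCTG
GTTCCCCGACTAACTTACATAGCCTTATCCGTAGAGTGTACCGTAACCCTAATACTCAATCTATGATTGT
ATGCGTGCGGACTGATCATTCTGAGGGGGCGCTCCCAACCCCGAACTGAAACAACATGGATTATCTAGCC
ATCGTCCCACAATCGGGACTGCGTGGAAGAAAAAAAAAAAAAAAAAAAAAAAAAAA
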