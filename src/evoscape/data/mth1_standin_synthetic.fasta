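>mth1_standin_synthetic synthetic 434-sense-codon CDS; 169 codons one substitution from a stop (stand-in for the MTH1 coding sequence, not the real gene)
CCAGTGACTCGCATTGAACCCCTTACATCCCTCTCCCAATCCTGCAGTCCTGAACTCTTG
TTGTGCGCTGGATCCCCTACAATCTCAGGTGAAAAACATGCGCGATATATCGCAAAGGTT
CGACCCAAGACCTCTAGAGCCCGGCGAGAGAGGTCGTTGACACCGGCGTACCGAAGGACG
ACTGAGGGGGAACTCCAAACCGTTATTGAAGGAGCGGCGACAACCAGAAAAAGGCTGAAT
TACGCGTTTACGAATAAGACAGGATACATATGTTCAATTCGAGACGGCAAACGACGGGAC
AGTCGAAAAAGACGGACAAAAAGTTCACAGTCACTTCAGTCTGAGCCATTCTCGTTGACA
GACGGGATGATTAGCTCGGAGAGAGCGCCCCGCTCGTACGCTAATGTCCTTCAGTATGAA
GCGTTTACAAGCACATTTCAGCCCAGCTCAAAACTTGTTGCACGTATTGTACCAGCACAG
ATCTGCGCCTGTCCTAATGGTGACGTCTCGCAGCAAGATATACAAAAAGGAAAGTATGAG
GATCTTAATTTAAGCACTGGTCGACGTTTGAAAATGATATGCAGCGAGGAAAGTGGGCCA
TTACAAGATCCGAACAGTATCAGACTCTCACAAACAGACAAGCACCGCAATTCAAGCACT
GAGAGCACCACGTTTACTGAATCAGCATGTGCCAGTTACGGTGGGCGGTCACAAAGGATT
GGACTCGGGCACTGGTCAGATGCTGAATACCAGGTGCCACAGAGTTGGTGTACTACTTTA
CAAAAGGCCTTTCATCATGGCTTGAACACTTTCTCTCATTTAAAAACAGATACAATCTGC
TACCATTTATGTCGTTCCGTTAAAGGAATTGGATTGGCGACAGCGACCTTTTCGTCAAGG
AATCACATGCTTAATTCTGTGTATTACACGCTGCACAATCCACAATCCCATGAAAGTCAC
GGGGCCAGCCCACCTAGATTCAAGGGAACCATGCTATCGCTGCTGTATGGGCGAGCTCAG
TGTTTGCCTGGGAACTCACGTTGCGACTGGGTTGTATCACCTCTTGTTCAGACGTCGTCC
ACTGGAGCTATGGAAGAGGGCCTAGAACGTACTAAACAGGAACAACGAGAGTCAGGTCGA
TTCATATTCCTCGGTGGCGGGAGCACCGAAAAACGACTGGTTGACAGTCGCCATGGTGTC
AAGGATGCTGTCAATTCACTGCAGGAGGCCGGGTTGTCTCGACTTCACCGGTTAGGACAG
TTAGGGCGTTTAGTTGCTAAAGAATGGGAGAAGCGTATTCCGTAA
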