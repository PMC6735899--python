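>toy_orf synthetic 300-codon ORF fixture
ATGCCGTTGCCAATTTTCAGCTTGGCGCAGGTACCTTGGAGGGACTCATACGAGACCAGT
ATTCAGCCCGATGATTCCGAAGTATTCCTTTTGAGAACAGCCAATAGACCAGAACCGAAA
CATGTCCGCTTAACATTATCGAAGCCATCGAGCATACAAGGGGGGCCTTCTGATGGTTAT
AGGGCAGCATTCCGACGTGCGATTACGCCGGATCAATTTTTTACGTACGGCTTCCAAGCT
TGGATGCGGTCCACTTCTTCCTGGCGTAGATATACATCGGCCTGTGGTCTGAGTCGTTTA
GGTATTAACGGAACCAGTCTCTTCCCGTCACTAACGTTCCACATCCCACAGAACCCCGAT
AGGAATTCGTATAGCCGCGAGCCTGAAGAGTTACGCGTAAGGGAAGTCCTTTCGTCACGC
GACACGGTCCCAGGCCATAAAACGCAGTTGAAGATAGAAGCTTCCGGCGCAGCCCCAATA
ATGATGTCCAGTTGCCCTTTGTCACTTAGAAGGACAGTTTATCTAACGTCATTTACTATT
GGGCGTATGTCTGAGTCCTGCGCCCCCCAGCCGGAAATTTGGCGGGCACCTGTGCGGGCC
CGGTTCCGATTGGGAGTAGCAATAGTAGCGAGTCGTACACCAATCTTGAGGTTACCAGTA
AGTACCCCTCTTGAATGTTCCGTTCTGGATTATATAACCTGCACGCCGCGCTTTTTATTA
GCACCTCACGGGATAGAGGACCTTCAATTGCAGTGGTATTCTGTCCCTAACGGAAACTCG
GCAGTCCATGCCGATCTGAAAATGTACGCGTTCTTTTGTCGGTACATGAGTAACACGGCT
GAAGAGAGCCCCTTGCAGAGTATGGAGAGACAGAGGACAGCATGTCCTGAGACGCCATTC
>toy_orf_flank5 synthetic amplicon 5' context
CATACGAGCTATCTACGTGCCTCAGCGATGGTTAACCCTTGTTACTGATC
>toy_orf_flank3 synthetic amplicon 3' context
GGCAAATGATGCGTGGCAGGCCAAACTCCTACGGTACTGCTGCTACCGTT
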