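>toy_mt
CCTACCGAAATGCTATGACATGAGCTTGGATGAACAGGCTGGATTCTACTGATCGTTCGTCAAAACAAGG
TCCCTCTCTACGTCCTGACCTGTATTCGCTAAGCTAGGCCTAGTCAGTTCTCTACGCTAACCACTTGGGG
CGCACGGCATCCGGACACTTGAGTCGAACTGACACGGCCTTCCAAAGGCTTAGAAGTCTTTCAATGAACG
TGCGAGTCGATAAACGATGTTCTTGACTTGCTTTATGAATAAGGCGGGAATTCCCGGGGATCCAAACATA
CAGATAGTGAAGTACGGGGTTAAAGTGACAGGGCACGCGTAGCATCCGGCGTCAGTGTGAACGCTAGCAG
CGCAAGGGAGCGGCCACCGCACCGAGAAGGCGCTCTTGAATGTCAATGTATGAACCCAGGGGTGGGGCGG
TCCTCCATAAACCCAGCCCGATGACAAGAGAGTTCGGAACCGGGGCTTTCATGCTTACTACACACTCTGT
CCCGTTAAAATAAGGCCTGCCCCGGCGATAAATGAAGGCTTGGATAGAGCCTTACCCCGGTACTCCTAGT
TTTACATAGATAAGCGTCCTGACTCAAGCCGCCGGTGATC
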