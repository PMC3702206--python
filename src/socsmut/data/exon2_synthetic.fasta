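>exon2_synthetic SOCS1-like exon-2 stand-in (synthetic sequence, 1766 bp; CDS 705..1340)
GGCGCTCGCGCGACGGCAACCACGACGCTTCAGGTCACCTCTTGGATCAGGCTCGGCAAGGCACTCGATG
AACGAATGTTGAACGGGACCGTAACCAAAAAAGGCCCTACCCCGACGTGAGGCCCGTCTTGCGATATATT
CAGCGTAAAGGAGGAGCATGTACCCTCACTATGGCAAGTAGTTCAACGACAATATCGGCGGACGTGCGTC
GTTTAAGCAGGCCTGGAGCTCCAACAGTGCGAGCGATTGAACGCCAGGACCACGATAGATAAGCCTCGGG
CAGTTGTTAGCCCCTACCAGGACTCCAATTATACCCGGAATTTGAAAAAATTGAATCGACTGGGTACGAC
GACAAAGGGTTACGTCTCCGACTAGAGTGTAGTATTAGTTATCAGCGTGGTGAAAAGGCATGCAGCTAAA
ACAAATTCATTTCTAATCAGTTCACATCTTTTTGACTTCAATAGCACAACAAGTGGGGCCCATGCGAAAA
AGGCTGAAGGTATGGCCGCCAAAGCCTGGCGTCACTTTCGGCGCGATGTACAGTTAAGGTGCGCCTTCTC
ACAGCCAACATTGGGTGGTTTGGCTGGACAGGTAAGCGGCGCGGATAATTGGAGCTGGAGGCCCGATTAT
GAGCGTCGGCATCACAATATGTCACGCAGATTCCTTAAGTGTCAAGACTCACCCCCGGACGCTATGATAT
TTTTATGAGTTATACAGACTTCGCAGCCCATCTAGTCGAAACGTTGGCCGCGCCACGCAGCGGTCCACCA
TTTGAGATTTACGTGTTACGAATTGCAACAGTCTGTATCACGTCGTTCGCCCGGACGGCTCCAAAAACTC
GTTCACCCCGGATGGGACTCTTCACAGGGGTTGTATCCGACGAGAGTCATGCCGTCGGACATAGCGGGCT
TAGGCCCCCTCCGTGCTGCATGGTCGTTCCCGGCTTACGTATTTTCGAGGCTTTAGACCCCGGAAACACA
CTCCGCCCGGATATTGAACTGCTCCGGCAATCTAGCGCGAAGGACAGTTTTTCCCACCTACTTGCACACT
TTAAAAAGAGGTCCCAGCAACACTCCACCTCGATGGATCCTCGGAGACGTGAGACTATGCTTTTTGCGAT
TGGTTGTAGCGGGGATTATATCAAATACCCGATACACGTACTGTGTATTTACATAGGGATTTTGGAGGTT
CAGCCCCTCCATCGTACGCGTGCTTACAGGTCAGCAGTGAAAGATTGCTACCCATTACACGTAGGCGATT
TCGAGCGGCGTGTAGTGTTTGTCCTATGGCAGTCACGCCCGCAGGCAAGGAAGTCGAGGTGTTACTTAAG
GTTCGGGTGAATCCTGACGGAATTATTTATAGAAGACGGGGGACGAGCCGTGATTAGAGGGAGCACTGAT
GAAACCCACACAACACGATTACTTGCCTGGAACCATGTGGCGCATGGAATACTCAGATTGAGTCTATGAT
AAACGGTCTGCAAGCGAAGTCCTACATGTCGGAAGGGGCGGGTTGCGTGATCCGTGAGTTGACTGCATCC
TTTGTCTGCGAGCTTCTTAGGCACACCGATCCTCGCCTGACATGATCTAGATACAGTCTCGCGCAGCAGA
AACACCCGGATTTCACAGCTTCTTACTAAATTCTTGGTTCTTCGAGATGTTTGCGAATTCATATATGATA
GAAACTCCGTAAAACTAGTGCTCCGGGCACTTGGAACATTGAGAACGGAGCACACACAAACTTCTGATTT
TATTATACAATACTGG
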