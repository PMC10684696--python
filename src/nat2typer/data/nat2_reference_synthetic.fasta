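>NAT2_4_reference_synthetic synthetic stand-in for the NAT2*4 873 bp coding exon
ATGAAGTTTGCCGCCCCGCGTGTTCCCTACAACGCTTCGACTCAACTCGTAACAGTCGAT
GCCTCGAAAGTTTAGTACACACAGCTGGTGGCGCAGCTTGCCAGTCAATAAACCGGAAAA
ACCAGAGCATGCTGCATAGGTGTAGGCTAATGCTGAAGCTGCCGCTAGGAGTTGCGATAT
TAAGGCCCCAGTCAGAACTCAACACAACGGAAAGGTCTAGGTGTATCCTGTAGGACGTCG
GAAGATACCCGAAACTGGCATTACCCAGCCGCTGAGCAAATCTTTGCACGTTAAAGACTG
CAGCATCCCAAGATCAGGATGTGGGGTTCTAAGGGTAGCCTACCCGCGTGGGCATGGTAT
GACTGAGGCGCTTATAACTAAAGCGATGTAGCAGAGTCGTTAACTTAATCAGCATAGTGT
TGTGGCTGGGAGAGACCTGGGGCTATTCATGATAAACACTTGCTCCCGGCGATTGCTGGA
CTGCTTGTATAGGAAGTACCCGGAGCGCTAACATTTAAAACATCCCGGTATCTTTTCCGT
CAATATATCCCTAGATCGGCAAGCGGGTACGTTGTGAGTGGTGAAACTAGGCGGGGAGGC
CCGATTCGGTTTAATCGTGAGTTGAAGGAACTGGTTCGGATAGCAATGACGGAATATGGA
AACTCCGGTGGGGTCAAGTGCAGTCATAGTTCATGCATCACATCTCCACGGATCATAGCG
TCACACTATCCGGCTCCCAGGCTAACGCCATTCATGTGCAATATTGCCTATAACGTATTG
AGAGTCTTGCGAACAACAAGCGACCTTGAAAAATAAAATAGGGTCATGCCAGGCCGTCTT
AAAGGTAGACGGGTCGGAATGATACTCCCCTTC
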