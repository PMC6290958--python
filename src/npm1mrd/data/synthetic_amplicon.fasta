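>npm1_exon12_synthetic_amplicon synthetic stand-in for the NPM1 exon-12 amplicon
TACGCATAAGCATTTGGCGTTAAGCGTCCATTAAAGGGCTGCGGCTTAAATTGGTCTAAAGGGAGTGAAG
GCATGTCCGTGAATACCAATAACTTCTGCTACTTTCTGATAGCACTCTGCATGGGATATGGCTCCAAGGG
AACATAGCCCTGACGAAGCGTAACGACTGTGACAACCAGCATATATATTAACGCATAAATACGACGAACC
ATACGCCAACCGTGACAGGTACTAATAGTGAGTCAGTGAC
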