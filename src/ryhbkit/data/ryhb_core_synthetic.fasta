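>ryhb_core_synthetic synthetic stand-in for a conserved ryhB core region; 90 nt; randomly generated, not from any real genome
GCCCTCTCCACCGGGGGTGGGCATGTGAGGTAAATCAAAAGTACGGGCATTATCATCTGC
ATGCACGGATTCGTACGTCGTACCAAGTAG
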