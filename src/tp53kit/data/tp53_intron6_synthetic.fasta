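>intron6 synthetic stand-in for TP53 intron 6 (3' end architecture only)
GTAAGTACTTAGGTTCATGCCTGTCTAACCATGATTGGCTTAGTCATACCTGACAGTTCTCTCCTTTCTC
CCTTCTCTTTCCTTCCCTCTTCTTTCCTCTCCCAG
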